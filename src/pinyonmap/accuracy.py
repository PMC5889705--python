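"""Design-based accuracy assessment and error-adjusted area estimation.

Implements the good-practice poststratified estimators for a stratified
accuracy-assessment sample cross-tabulated against reference data, with
mapped class areas as stratum weights:

    p-hat_ij = W_i * n_ij / n_i.                 (proportion-of-area cell)
    p-hat_.j = sum_i W_i * n_ij / n_i.           (reference-class total)
    A-hat_j  = A * p-hat_.j                      (error-adjusted area)
    S(p-hat_.j) = sqrt( sum_i W_i^2 * r_ij (1 - r_ij) / (n_i. - 1) ),
                  r_ij = n_ij / n_i.             (standard error)
    S(A-hat_j)  = A * S(p-hat_.j)

Overall accuracy is the trace of the proportion matrix, user's accuracy
the diagonal over row totals, producer's accuracy the diagonal over
column totals. Conventions are fixed as map classes on rows, reference
classes on columns. A chance-corrected kappa is provided on either the
raw-count or the proportion-of-area basis.

Confidence intervals are reported both as ``ci_multiplier * SE`` (default
1.96, the approximate 95% normal interval) and as the plain ``2 * SE``
margin, since published area margins are often the latter; both are
labelled in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, EstimationError


@dataclass
class ErrorMatrix:
    """Sample counts (map rows x reference columns) plus mapped areas.

    Invariants: counts nonnegative integers; every map class has positive
    mapped area wherever it has sample counts; weights sum to one.
    """

    class_names: tuple[str, ...]
    counts: np.ndarray
    mapped_areas: np.ndarray

    def __post_init__(self) -> None:
        self.class_names = tuple(self.class_names)
        self.counts = np.asarray(self.counts)
        self.mapped_areas = np.asarray(self.mapped_areas, dtype=float)
        q = len(self.class_names)
        if self.counts.shape != (q, q):
            raise DataError(f"counts must be {q}x{q}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise DataError("negative sample counts")
        if np.mod(self.counts, 1).any():
            raise DataError("non-integer sample counts")
        if self.mapped_areas.shape != (q,):
            raise DataError("one mapped area per map class required")
        if (self.mapped_areas < 0).any() or self.total_area <= 0:
            raise DataError("mapped areas must be nonnegative with positive total")
        zero_area = (self.mapped_areas == 0) & (self.row_totals > 0)
        if zero_area.any():
            bad = [self.class_names[i] for i in np.nonzero(zero_area)[0]]
            raise DataError(f"classes with samples but zero mapped area: {bad}")

    @property
    def q(self) -> int:
        return len(self.class_names)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def total_area(self) -> float:
        return float(self.mapped_areas.sum())

    @property
    def weights(self) -> np.ndarray:
        return self.mapped_areas / self.total_area

    def row_agreement_rates(self) -> np.ndarray:
        """Per map class, the share of its samples whose reference class agrees.

        These are the raw-count row rates (e.g. 522/536 for a pine row);
        their complements are the row error proportions.
        """
        totals = self.row_totals
        with np.errstate(invalid="ignore"):
            return np.where(totals > 0, np.diag(self.counts) / totals, np.nan)


def build_error_matrix(samples: pd.DataFrame,
                       mapped_areas: Mapping[str, float],
                       class_names: tuple[str, ...] | None = None) -> ErrorMatrix:
    """Cross-tabulate a reference sample carrying ``mapped_class`` and ``true_class``."""
    if len(samples) == 0:
        raise DataError("empty sample table")
    for col in ("mapped_class", "true_class"):
        if col not in samples.columns:
            raise DataError(f"sample table lacks column {col!r}")
    names = tuple(class_names) if class_names else tuple(mapped_areas.keys())
    unknown = (set(samples["mapped_class"]) | set(samples["true_class"])) - set(names)
    if unknown:
        raise DataError(f"sample classes not in class roster: {sorted(unknown)}")
    idx = {c: i for i, c in enumerate(names)}
    q = len(names)
    counts = np.zeros((q, q), dtype=int)
    for m, t in zip(samples["mapped_class"], samples["true_class"]):
        counts[idx[m], idx[t]] += 1
    areas = np.array([float(mapped_areas[c]) for c in names])
    return ErrorMatrix(class_names=names, counts=counts, mapped_areas=areas)


def poststratified_proportions(em: ErrorMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Proportion-of-area matrix p-hat_ij and its column totals p-hat_.j."""
    totals = em.row_totals
    if (totals == 0).any():
        bad = [em.class_names[i] for i in np.nonzero(totals == 0)[0]]
        raise EstimationError(f"strata with zero samples: {bad}")
    p_hat = em.weights[:, None] * em.counts / totals[:, None]
    return p_hat, p_hat.sum(axis=0)


def proportion_se(em: ErrorMatrix) -> np.ndarray:
    """Standard errors of the reference-class proportion totals p-hat_.j."""
    totals = em.row_totals
    r = em.counts / totals[:, None]
    numer = r * (1 - r)
    denom = (totals - 1)[:, None]
    off_diag = em.counts - np.diag(np.diag(em.counts))
    singleton = (totals == 1) & (off_diag.sum(axis=1) > 0)
    if singleton.any():
        i = int(np.nonzero(singleton)[0][0])
        raise EstimationError(
            f"stratum {em.class_names[i]!r} has a single sample with off-diagonal "
            "counts; variance undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(numer > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    var = (em.weights[:, None] ** 2 * terms).sum(axis=0)
    return np.sqrt(var)


def estimate_areas(em: ErrorMatrix, ci_multiplier: float = 1.96) -> dict[str, np.ndarray]:
    """Error-adjusted areas with standard errors and interval half-widths."""
    _, col_totals = poststratified_proportions(em)
    se_p = proportion_se(em)
    A = em.total_area
    areas = A * col_totals
    se_area = A * se_p
    return {
        "proportions": col_totals,
        "proportion_se": se_p,
        "areas": areas,
        "area_se": se_area,
        "half_width": ci_multiplier * se_area,
        "margin_2se": 2.0 * se_area,
        "ci_multiplier": ci_multiplier,
    }


def accuracies(em: ErrorMatrix) -> tuple[float, np.ndarray, np.ndarray]:
    """(overall, user's per map class, producer's per reference class).

    Producer's accuracy for an empty reference column is NaN rather than
    an exception — the class simply never appears in the reference data.
    """
    p_hat, col_totals = poststratified_proportions(em)
    overall = float(np.trace(p_hat))
    row_totals = p_hat.sum(axis=1)
    users = np.diag(p_hat) / row_totals
    with np.errstate(invalid="ignore", divide="ignore"):
        producers = np.where(col_totals > 0, np.diag(p_hat) / np.where(col_totals > 0, col_totals, 1.0), np.nan)
    return overall, users, producers


def kappa(em: ErrorMatrix, basis: str = "counts") -> float:
    """Chance-corrected agreement K = (p_o - p_e) / (1 - p_e).

    ``basis='counts'`` uses the raw sample counts, ``basis='area_proportions'``
    the poststratified proportion matrix. Returns NaN for the degenerate
    single-class case where chance agreement is one.
    """
    if basis == "counts":
        mat = em.counts / em.n
    elif basis == "area_proportions":
        mat, _ = poststratified_proportions(em)
    else:
        raise DataError(f"unknown kappa basis {basis!r}")
    nz = (mat.sum(axis=1) > 0) | (mat.sum(axis=0) > 0)
    if nz.sum() < 2:
        return float("nan")
    p_o = float(np.trace(mat))
    p_e = float((mat.sum(axis=1) * mat.sum(axis=0)).sum())
    if p_e >= 1.0:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class AreaReport:
    """Full inference report from one error matrix."""

    class_names: tuple[str, ...]
    p_hat: np.ndarray
    column_totals: np.ndarray
    areas: np.ndarray
    area_se: np.ndarray
    half_width: np.ndarray
    margin_2se: np.ndarray
    overall: float
    users: np.ndarray
    producers: np.ndarray
    kappa_counts: float
    kappa_area: float
    ci_multiplier: float
    total_area: float
    row_agreement: np.ndarray

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "p_hat": self.p_hat.tolist(),
            "column_totals": self.column_totals.tolist(),
            "areas": self.areas.tolist(),
            "area_se": self.area_se.tolist(),
            "half_width": self.half_width.tolist(),
            "margin_2se": self.margin_2se.tolist(),
            "overall": self.overall,
            "users": self.users.tolist(),
            "producers": self.producers.tolist(),
            "kappa_counts": self.kappa_counts,
            "kappa_area": self.kappa_area,
            "ci_multiplier": self.ci_multiplier,
            "total_area": self.total_area,
            "row_agreement": self.row_agreement.tolist(),
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    def format_table(self) -> str:
        """Text table of proportions and accuracies, rounded for display."""
        w = max(9, max(len(c) for c in self.class_names))
        lines = [f"{'class':>{w}}  " + "  ".join(f"{c:>9}" for c in self.class_names)
                 + "      user  producer"]
        for i, c in enumerate(self.class_names):
            cells = "  ".join(f"{self.p_hat[i, j]:9.4f}" for j in range(len(self.class_names)))
            prod = f"{self.producers[i]:8.3f}" if np.isfinite(self.producers[i]) else "      NA"
            lines.append(f"{c:>{w}}  {cells}  {self.users[i]:8.3f}  {prod}")
        totals = "  ".join(f"{t:9.4f}" for t in self.column_totals)
        lines.append(f"{'total':>{w}}  {totals}")
        lines.append(f"overall accuracy {self.overall:.4f}   kappa(counts) {self.kappa_counts:.4f}")
        for j, c in enumerate(self.class_names):
            lines.append(
                f"area[{c}] = {self.areas[j]:.1f} +/- {self.half_width[j]:.1f} "
                f"({self.ci_multiplier} SE; 2 SE margin {self.margin_2se[j]:.1f})")
        return "\n".join(lines)


def area_report(em: ErrorMatrix, ci_multiplier: float = 1.96) -> AreaReport:
    """Compute the complete report: proportions, areas, SEs, accuracies, kappa."""
    p_hat, col_totals = poststratified_proportions(em)
    est = estimate_areas(em, ci_multiplier)
    overall, users, producers = accuracies(em)
    return AreaReport(
        class_names=em.class_names,
        p_hat=p_hat,
        column_totals=col_totals,
        areas=est["areas"],
        area_se=est["area_se"],
        half_width=est["half_width"],
        margin_2se=est["margin_2se"],
        overall=overall,
        users=users,
        producers=producers,
        kappa_counts=kappa(em, "counts"),
        kappa_area=kappa(em, "area_proportions"),
        ci_multiplier=ci_multiplier,
        total_area=em.total_area,
        row_agreement=em.row_agreement_rates(),
    )


def read_error_matrix_csv(path: str | Path) -> ErrorMatrix:
    """Parse an error-matrix CSV.

    Layout: header ``map_class,<ref class...>,mapped_area``; one row per
    map class with integer reference counts and a trailing mapped area.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as parse error
        raise DataError(f"cannot parse {path}: {exc}") from exc
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "map_class" or cols[-1] != "mapped_area":
        raise DataError(
            f"{path}: expected columns map_class,<ref classes...>,mapped_area, got {cols}")
    ref_classes = cols[1:-1]
    map_classes = list(df["map_class"])
    if sorted(map_classes) != sorted(ref_classes):
        raise DataError(f"{path}: map rows {map_classes} do not match reference columns {ref_classes}")
    # reorder rows to the reference-column order so the matrix is square-aligned
    df = df.set_index("map_class").loc[ref_classes]
    counts = df[ref_classes].to_numpy()
    for line, row in enumerate(counts, start=2):
        if (np.asarray(row) < 0).any():
            raise DataError(f"{path}: negative count on line {line}")
    areas = df["mapped_area"].to_numpy(dtype=float)
    return ErrorMatrix(class_names=tuple(ref_classes), counts=counts, mapped_areas=areas)


def assess_from_csv(matrix_csv: str | Path, ci_multiplier: float = 1.96) -> AreaReport:
    """End-to-end: parse an error-matrix CSV and produce the full report."""
    return area_report(read_error_matrix_csv(matrix_csv), ci_multiplier)
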