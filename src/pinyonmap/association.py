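"""Presence/absence association modelling against terrain and climate covariates.

The screening-and-modelling chain used for species distribution work on a
focal class:

1. Kruskal-Wallis rank test per covariate between presence and absence
   groups, keeping variables significant after a Bonferroni-style cutoff
   (default alpha = 0.0005).
2. Collinearity pruning: among retained covariates, any pair with
   Spearman |r_s| above a threshold (default 0.7) keeps only the member
   with the smaller Kruskal-Wallis p-value. Pairs are processed in
   ascending-p order so the outcome is deterministic.
3. A binomial logistic regression on the retained covariates, reported
   with estimates, standard errors, Wald z and p-values, AIC and residual
   deviance (statsmodels GLM under the hood).
4. Stratified k-fold cross-validated random-forest classification
   (scikit-learn forest), scored with AUC, sensitivity, specificity,
   TSS = sensitivity + specificity - 1, and binary kappa at a fixed 0.5
   threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
import statsmodels.api as sm

from .errors import ConfigError, DataError, FitError


# -- elementary statistics ----------------------------------------------


def kruskal_wallis_two_group(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Two-group Kruskal-Wallis H with tie correction; p from chi-square df=1.

    An all-tied pooled sample has no rank separation at all and returns
    (0, 1) rather than raising.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise DataError(f"need exactly two groups, got {len(labels)}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(a, b)
    return float(h), float(p)


def spearman_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation; NaN for a constant input vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("inputs must share length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, _ = stats.spearmanr(x, y)
    return float(r)


def true_skill_statistic(sensitivity: float, specificity: float) -> float:
    """TSS = sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


# -- screening ----------------------------------------------------------


@dataclass
class ScreeningReport:
    """Audit trail of the two-stage covariate screen."""

    kw_table: pd.DataFrame           # variable, H, p, passed
    pruning_log: list[dict] = field(default_factory=list)  # kept, dropped, r_s
    retained: list[str] = field(default_factory=list)
    alpha: float = 0.0005
    rs_threshold: float = 0.7

    @property
    def empty(self) -> bool:
        return len(self.retained) == 0

    def to_dict(self) -> dict:
        return {
            "kw_table": self.kw_table.to_dict(orient="records"),
            "pruning_log": self.pruning_log,
            "retained": self.retained,
            "alpha": self.alpha,
            "rs_threshold": self.rs_threshold,
        }


def screen_variables(table: pd.DataFrame, covariates: Sequence[str] | None = None,
                     presence_col: str = "presence", alpha: float = 0.0005,
                     rs_threshold: float = 0.7) -> ScreeningReport:
    """Kruskal-Wallis significance screen followed by Spearman pruning.

    Stage 1 drops covariates whose two-group Kruskal-Wallis p is at or
    above ``alpha``. Stage 2 walks the survivors in ascending-p order and,
    for any pair with |r_s| above ``rs_threshold``, drops the member with
    the larger p. An empty retained set is flagged, not an exception.
    """
    if covariates is None:
        covariates = [c for c in table.columns if c != presence_col]
    if len(covariates) < 2:
        raise DataError("need at least two candidate covariates to screen")
    y = table[presence_col].to_numpy()
    rows = []
    for var in covariates:
        h, p = kruskal_wallis_two_group(table[var].to_numpy(), y)
        rows.append({"variable": var, "H": h, "p": p, "passed": bool(p < alpha)})
    kw = pd.DataFrame(rows)
    survivors = kw[kw["passed"]].sort_values("p", kind="stable")
    order = list(survivors["variable"])
    pvals = dict(zip(kw["variable"], kw["p"]))
    dropped: set[str] = set()
    log: list[dict] = []
    for i, keep in enumerate(order):
        if keep in dropped:
            continue
        for other in order[i + 1:]:
            if other in dropped:
                continue
            rs = spearman_correlation(table[keep].to_numpy(), table[other].to_numpy())
            if np.isfinite(rs) and abs(rs) > rs_threshold:
                dropped.add(other)
                log.append({"kept": keep, "dropped": other, "r_s": rs,
                            "p_kept": pvals[keep], "p_dropped": pvals[other]})
    retained = [v for v in order if v not in dropped]
    return ScreeningReport(kw_table=kw, pruning_log=log, retained=retained,
                           alpha=alpha, rs_threshold=rs_threshold)


# -- logistic regression ------------------------------------------------


@dataclass
class LogisticFit:
    """Binomial logistic regression results (inference table + fit stats)."""

    terms: list[str]                 # "Intercept" first
    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    aic: float
    deviance: float
    df_resid: int
    converged: bool
    nobs: int

    def coefficient(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.bse[self.terms.index(term)])

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "estimate": self.params.tolist(),
            "std_error": self.bse.tolist(),
            "z_value": self.zvalues.tolist(),
            "p_value": self.pvalues.tolist(),
            "aic": self.aic,
            "residual_deviance": self.deviance,
            "df_residual": self.df_resid,
            "converged": self.converged,
            "nobs": self.nobs,
        }

    def format_table(self) -> str:
        lines = [f"binomial logistic regression  (AIC = {self.aic:.1f}; "
                 f"residual deviance = {self.deviance:.2f} on {self.df_resid} degrees of freedom)",
                 f"{'Variable':>10}  {'Estimate':>10}  {'Std. Error':>10}  {'Z value':>8}  Pr(>|z|)"]
        for i, t in enumerate(self.terms):
            lines.append(f"{t:>10}  {self.params[i]:10.3f}  {self.bse[i]:10.3f}  "
                         f"{self.zvalues[i]:8.3f}  {self.pvalues[i]:.4g}")
        return "\n".join(lines)


def fit_logistic(table: pd.DataFrame, covariates: Sequence[str],
                 presence_col: str = "presence") -> LogisticFit:
    """Maximum-likelihood binomial logistic fit with a Wald inference table.

    Raises :class:`FitError` on rank deficiency or (quasi-)separation,
    naming the offending covariate where identifiable.
    """
    y = table[presence_col].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise DataError("both presence classes must be present")
    X = table[list(covariates)].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError("rank-deficient design matrix")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = model.fit()
        except PerfectSeparationWarning as exc:
            raise FitError(f"perfect separation in logistic fit: {exc}") from exc
        except Exception as exc:  # noqa: BLE001
            raise FitError(f"logistic fit failed: {exc}") from exc
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    huge = ~np.isfinite(bse) | (np.abs(params) > 1e3) | (bse > 1e5)
    if huge.any():
        terms = ["Intercept"] + list(covariates)
        bad = [terms[i] for i in np.nonzero(huge)[0]]
        raise FitError(f"apparent separation / diverging estimates for terms {bad}")
    return LogisticFit(
        terms=["Intercept"] + list(covariates),
        params=params,
        bse=bse,
        zvalues=np.asarray(res.tvalues),
        pvalues=np.asarray(res.pvalues),
        aic=float(res.aic),
        deviance=float(res.deviance),
        df_resid=int(res.df_resid),
        converged=bool(res.converged),
        nobs=int(res.nobs),
    )


def predict_occurrence(fit: LogisticFit, covariates: Mapping[str, float] | pd.DataFrame):
    """Occurrence probability: inverse logit of the fitted linear predictor."""
    names = fit.terms[1:]
    if isinstance(covariates, pd.DataFrame):
        missing = [t for t in names if t not in covariates.columns]
        if missing:
            raise ConfigError(f"missing model terms: {missing}")
        X = covariates[names].to_numpy(dtype=float)
        lp = fit.params[0] + X @ fit.params[1:]
        return expit(lp)
    missing = [t for t in names if t not in covariates]
    if missing:
        raise ConfigError(f"missing model terms: {missing}")
    lp = fit.params[0] + sum(fit.coefficient(t) * float(covariates[t]) for t in names)
    return float(expit(lp))


# -- classification metrics and cross-validation ------------------------


def classification_metrics(scores: np.ndarray, labels: np.ndarray,
                           threshold: float = 0.5) -> dict[str, float]:
    """AUC (rank formulation), sensitivity, specificity, TSS and kappa.

    Sensitivity/specificity/kappa are taken at the given score threshold;
    TSS is their identity combination.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise DataError("metrics need both classes present")
    auc = float(roc_auc_score(labels, scores))
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    kap = float(cohen_kappa_score(labels, pred))
    return {
        "auc": auc,
        "sensitivity": sens,
        "specificity": spec,
        "tss": true_skill_statistic(sens, spec),
        "kappa": kap,
    }


@dataclass
class CVReport:
    """Per-fold and mean validation metrics of the cross-validated forest."""

    fold_metrics: pd.DataFrame       # one row per fold
    fold_assignments: np.ndarray     # fold index per sample
    seed: int

    @property
    def means(self) -> pd.Series:
        return self.fold_metrics[["auc", "sensitivity", "specificity", "tss", "kappa"]].mean()

    def to_dict(self) -> dict:
        return {
            "fold_metrics": self.fold_metrics.to_dict(orient="records"),
            "means": self.means.to_dict(),
            "fold_assignments": self.fold_assignments.tolist(),
            "seed": self.seed,
        }


def random_forest_cv(table: pd.DataFrame, covariates: Sequence[str],
                     presence_col: str = "presence", k: int = 10,
                     seed: int = 0, n_estimators: int = 500,
                     threshold: float = 0.5) -> CVReport:
    """Stratified k-fold cross-validated random forest on a presence table.

    Fold construction is stratified and seeded; each held-out fold is
    scored with :func:`classification_metrics` on the forest's predicted
    presence probability.
    """
    y = table[presence_col].to_numpy(dtype=int)
    X = table[list(covariates)].to_numpy(dtype=float)
    if len(table) < k:
        raise DataError(f"n = {len(table)} < k = {k}")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise DataError(
            f"minority class has {counts.min()} samples; cannot build {k} stratified folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.full(len(y), -1, dtype=int)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        assignments[test_idx] = fold
        if len(np.unique(y[test_idx])) < 2:
            raise DataError(f"fold {fold} lacks a class despite stratification")
        rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        rf.fit(X[train_idx], y[train_idx])
        prob = rf.predict_proba(X[test_idx])[:, list(rf.classes_).index(1)]
        m = classification_metrics(prob, y[test_idx], threshold=threshold)
        m["fold"] = fold
        rows.append(m)
    return CVReport(fold_metrics=pd.DataFrame(rows), fold_assignments=assignments,
                    seed=seed)
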