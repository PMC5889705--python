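"""End-to-end orchestration: generate -> terrain/indices -> classify -> assess -> associate.

Each stage writes its outputs to disk (text rasters, CSV tables, JSON
reports) so stages are independently inspectable and a run can be
reproduced byte-for-byte from the same config and seed. All randomness
flows from one root seed, split into fixed per-stage streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accuracy, association, synthetic
from .classifier import BackpropPixelClassifier, TrainConfig, predict_map
from .errors import PinyonError
from .grid import CATEGORICAL, Grid, write_ascii_grid
from .spectral import build_stack, write_stack
from .synthetic import SceneConfig
from .terrain import compute_terrain

logger = logging.getLogger("pinyonmap")

#: packaged worked example: the published four-class error matrix with
#: mapped areas (pine / scrub / chaparral / no-apparent-vegetation)
TABLE3_FIXTURE = Path(__file__).parent / "data" / "table3.csv"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    ci_multiplier: float = 1.96
    kappa_basis: str = "counts"
    alpha: float = 0.0005
    rs_threshold: float = 0.7
    k_folds: int = 10
    n_trees: int = 500
    n_env_samples: int = 592
    assessment_samples_per_class: int = 400
    output_dir: str = "pinyon_run"
    seed: int = 0
    log_level: str = "INFO"

    def reseeded(self, seed: int) -> "RunConfig":
        cfg = dataclasses.replace(self, seed=int(seed))
        cfg.scene = dataclasses.replace(self.scene, seed=int(seed))
        cfg.train = dataclasses.replace(self.train, seed=int(seed))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scene = SceneConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in raw.pop("scene", {}).items()})
        train = TrainConfig(**raw.pop("train", {}))
        return cls(scene=scene, train=train, **raw)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    report_paths: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], elapsed: float) -> None:
        for p in outputs:
            if not Path(p).exists():
                raise PinyonError(f"stage {stage}: output {p} missing at manifest time")
        self.stages.append({
            "stage": stage,
            "outputs": [str(p) for p in outputs],
            "seconds": round(elapsed, 3),
        })

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": self.stages,
            "reports": self.report_paths,
        }, indent=1))
        return path


def _stage(manifest: RunManifest, name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s start (config %s)", name, manifest.config_hash)
            self.t0 = time.perf_counter()
            self.outputs: list[Path] = []
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s failed: %s", name, exc)
                raise PinyonError(f"stage {name!r} failed: {exc}") from exc
            manifest.record(name, self.outputs, time.perf_counter() - self.t0)
            logger.info("stage %s done", name)
            return False
    return _Ctx()


def classify_scene(scene: dict, train_cfg: TrainConfig):
    """Train the backprop classifier on a truth-stratified sample and map the scene.

    Returns (stack, model, class_map grid, probability grid, training table).
    """
    cfg: SceneConfig = scene["config"]
    stack = build_stack(scene["bands"])
    train_table = synthetic.sample_reference(scene["cover"], cfg)
    X = stack.features_at(train_table["row"].to_numpy(), train_table["col"].to_numpy())
    y = np.array([cfg.class_code(c) for c in train_table["true_class"]])
    model = BackpropPixelClassifier(
        hidden_dim=train_cfg.hidden_dim, learning_rate=train_cfg.learning_rate,
        max_iterations=train_cfg.max_iterations, target_rms=train_cfg.target_rms,
        random_state=train_cfg.seed).fit(X, y)
    class_map, prob_map = predict_map(model, stack)
    return stack, model, class_map, prob_map, train_table


def assessment_sample(class_map: Grid, cover: Grid, cfg: SceneConfig,
                      per_class: int, seed_offset: int = 1) -> pd.DataFrame:
    """Accuracy-assessment sample: stratified by MAP class, truth looked up.

    The design stratifies on the mapped classes (the strata the area
    weights refer to), then reads the reference class off the truth map.
    """
    sample_cfg = dataclasses.replace(cfg, seed=cfg.seed + 100_003 * seed_offset,
                                     samples_per_class=per_class)
    table = synthetic.sample_reference(class_map, sample_cfg)
    table = table.rename(columns={"true_class": "mapped_class"})
    truth_codes = cover.values[table["row"].to_numpy(), table["col"].to_numpy()]
    table["true_class"] = [cfg.class_names[c] for c in truth_codes]
    return table


def mapped_areas_ha(class_map: Grid, cfg: SceneConfig) -> dict[str, float]:
    """Mapped area per class in hectares from the class map's cell counts."""
    cell_ha = (class_map.cell_size ** 2) / 10_000.0
    areas = {}
    for i, name in enumerate(cfg.class_names):
        areas[name] = float(((class_map.values == i) & ~class_map.nodata_mask).sum()) * cell_ha
    return areas


def build_env_table(scene: dict, n_samples: int, seed: int) -> pd.DataFrame:
    """Presence/absence table over the pine-eligible zone with env covariates."""
    cfg: SceneConfig = scene["config"]
    dem = scene["dem"]
    terr = scene["terrain"]
    cov = scene["covariates"]
    eligible = (dem.values >= cfg.pine_elevation_floor) & ~dem.nodata_mask
    rr, cc = np.nonzero(eligible)
    if rr.size < n_samples:
        raise PinyonError(
            f"only {rr.size} eligible cells for {n_samples} environment samples")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 9001)))
    pick = rng.choice(rr.size, size=n_samples, replace=False)
    rr, cc = rr[pick], cc[pick]
    pine_code = cfg.class_code("pine")
    table = pd.DataFrame({
        "presence": (scene["cover"].values[rr, cc] == pine_code).astype(int),
        "TRI": terr["TRI"].values[rr, cc],
        "VRM": terr["VRM"].values[rr, cc],
        "S": terr["slope"].values[rr, cc],
        "A": np.where(terr["aspect"].nodata_mask[rr, cc], 0.0,
                      terr["aspect"].values[rr, cc]),
        "E": dem.values[rr, cc],
        "MTWM": cov["MTWM"].values[rr, cc],
        "MMAX": cov["MMAX"].values[rr, cc],
        "NOISE1": cov["NOISE1"].values[rr, cc],
        "NOISE2": cov["NOISE2"].values[rr, cc],
    })
    return table


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage in order, writing all intermediates under output_dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed)
    cfg = config.scene

    with _stage(manifest, "generate") as st:
        scene = synthetic.generate_scene(cfg)
        st.outputs.append(write_ascii_grid(scene["dem"], out / "dem.asc"))
        st.outputs.append(write_ascii_grid(scene["cover"], out / "cover_truth.asc"))
        for name, g in scene["covariates"].items():
            st.outputs.append(write_ascii_grid(g, out / f"cov_{name}.asc"))

    with _stage(manifest, "terrain") as st:
        for name, g in scene["terrain"].items():
            st.outputs.append(write_ascii_grid(g, out / f"terrain_{name}.asc"))

    with _stage(manifest, "classify") as st:
        stack, model, class_map, prob_map, train_table = classify_scene(scene, config.train)
        st.outputs.append(write_stack(stack, out / "stack"))
        st.outputs.append(model.to_json(out / "model.json"))
        st.outputs.append(write_ascii_grid(class_map, out / "class_map.asc"))
        st.outputs.append(write_ascii_grid(prob_map, out / "probability_map.asc"))
        train_path = out / "training_sample.csv"
        train_table.to_csv(train_path, index=False)
        st.outputs.append(train_path)

    with _stage(manifest, "assess") as st:
        samples = assessment_sample(class_map, scene["cover"], cfg,
                                    config.assessment_samples_per_class)
        areas = mapped_areas_ha(class_map, cfg)
        em = accuracy.build_error_matrix(samples, areas, class_names=cfg.class_names)
        report = accuracy.area_report(em, ci_multiplier=config.ci_multiplier)
        sample_path = out / "assessment_sample.csv"
        samples.to_csv(sample_path, index=False)
        st.outputs.append(sample_path)
        st.outputs.append(report.to_json(out / "area_report.json"))
        (out / "area_report.txt").write_text(report.format_table() + "\n")
        st.outputs.append(out / "area_report.txt")
        manifest.report_paths["area_report"] = str(out / "area_report.json")

    with _stage(manifest, "associate") as st:
        env = build_env_table(scene, config.n_env_samples, config.seed)
        env_path = out / "env_samples.csv"
        env.to_csv(env_path, index=False)
        st.outputs.append(env_path)
        screen = association.screen_variables(
            env, alpha=config.alpha, rs_threshold=config.rs_threshold)
        screen_path = out / "screening.json"
        screen_path.write_text(json.dumps(screen.to_dict(), indent=1))
        st.outputs.append(screen_path)
        assoc: dict = {"screening_retained": screen.retained}
        if not screen.empty:
            fit = association.fit_logistic(env, screen.retained)
            assoc["logistic"] = fit.to_dict()
            (out / "logistic_table.txt").write_text(fit.format_table() + "\n")
            st.outputs.append(out / "logistic_table.txt")
            cv = association.random_forest_cv(env, screen.retained,
                                             k=config.k_folds, seed=config.seed,
                                             n_estimators=config.n_trees)
            assoc["random_forest_cv"] = cv.to_dict()
        assoc_path = out / "association_report.json"
        assoc_path.write_text(json.dumps(assoc, indent=1))
        st.outputs.append(assoc_path)
        manifest.report_paths["association_report"] = str(assoc_path)

    manifest.to_json(out / "manifest.json")
    return manifest


def assess_from_csv(matrix_csv: str | Path, ci_multiplier: float = 1.96) -> accuracy.AreaReport:
    """Reproduce the proportion/accuracy/area report from an error-matrix CSV."""
    return accuracy.assess_from_csv(matrix_csv, ci_multiplier)
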