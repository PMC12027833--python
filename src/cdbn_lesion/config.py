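"""Pipeline configuration, validation, seeding, and end-to-end execution.

A single YAML/JSON file configures all stages. Every hyperparameter that
the evolutionary search explores is validated against its search range at
load time, so an infeasible run fails before any training. One master seed
fans out to per-stage seeds through a documented stage-name hash, so any
stage can be rerun in isolation with the seed the full run used.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cdbn import (
    CDBNConfig,
    CDBNModel,
    DEFAULT_LAYER_SPECS,
    LayerSpec,
    extract_features_batch,
    train_layerwise,
    validate_dimension_chain,
)
from .classify import EvalReport, evaluate, stratified_split, train_classifier
from .gabor import GABOR_BOUNDS, GaborParams, apply_gabor
from .synth import PatchDataset

logger = logging.getLogger("cdbn_lesion")

__all__ = [
    "PipelineConfig",
    "load_config",
    "stage_seed",
    "run_pipeline",
    "ConfigFileError",
]

_SEARCH_BOUNDS: dict[str, tuple[float, float]] = {
    **GABOR_BOUNDS,
    "p1": (0.0, 1.0),
    "p2": (0.0, 1.0),
    "alpha1": (1e-9, 1e-5),
    "alpha2": (1e-9, 1e-5),
    "alpha3": (1e-9, 1e-5),
}


class ConfigFileError(ValueError):
    """Raised for unparseable, unknown-key, or out-of-range configuration."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC-32 of the stage name XOR master."""
    return (zlib.crc32(stage.encode("utf-8")) ^ (master_seed & 0xFFFFFFFF)) % (2**31)


@dataclass
class PipelineConfig:
    """Validated configuration for the full patch-classification pipeline.

    Defaults: the published optimum of the evolutionary search for the
    Gabor filter, the three-layer 256-feature architecture, 100 boosted
    trees, stratified 80/20 evaluation split.
    """

    # gabor block: the best parameter vector found by the RCGA search
    gabor: GaborParams = field(
        default_factory=lambda: GaborParams(
            sigma=197.8324, theta=0.4148, lam=14.6398, psi=0.4470, gamma=0.9831, k=71.3538
        )
    )
    # cdbn block
    layers: tuple[LayerSpec, ...] = DEFAULT_LAYER_SPECS
    alphas: tuple[float, float, float] = (1e-5, 1e-5, 1e-5)
    p1: float = 0.5
    p2: float = 0.5
    epochs: int = 5
    batch_size: int = 32
    cd_steps: int = 1
    # classifier block
    n_trees: int = 100
    test_fraction: float = 0.2
    # search block
    search_algorithm: str = "rcga"
    population: int = 10
    generations: int = 20
    # global
    seed: int = 0

    def cdbn_config(self, seed: int | None = None) -> CDBNConfig:
        n = len(self.layers)
        n_inner = max(n - 1, 0)
        thresholds = ((self.p1, self.p2) + (0.5,) * n_inner)[:n_inner]
        # positional alpha -> layer mapping; extra layers reuse the last rate
        alphas = (tuple(self.alphas) + (self.alphas[-1],) * n)[:n]
        return CDBNConfig(
            layers=self.layers,
            learning_rates=alphas,
            pool_thresholds=thresholds,
            epochs=self.epochs,
            batch_size=self.batch_size,
            cd_steps=self.cd_steps,
            seed=self.seed if seed is None else seed,
        )


_GABOR_KEYS = ("sigma", "theta", "lam", "psi", "gamma", "k")
_CDBN_KEYS = ("layers", "alpha1", "alpha2", "alpha3", "p1", "p2", "epochs", "batch_size", "cd_steps")
_CLASSIFIER_KEYS = ("n_trees", "test_fraction")
_SEARCH_KEYS = ("algorithm", "population", "generations")
_TOP_KEYS = ("gabor", "cdbn", "classifier", "search", "seed")


def _check_range(name: str, value: float) -> float:
    lo, hi = _SEARCH_BOUNDS[name]
    value = float(value)
    if not lo <= value <= hi:
        raise ConfigFileError(f"{name}={value} outside its range [{lo}, {hi}]")
    return value


def _reject_unknown(block: dict, allowed: tuple[str, ...], where: str) -> None:
    unknown = set(block) - set(allowed)
    if unknown:
        raise ConfigFileError(f"unknown key(s) {sorted(unknown)} in {where}; allowed: {list(allowed)}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML/JSON pipeline config; fill defaults.

    An empty file yields the full default configuration. Unknown keys and
    values outside the printed hyperparameter ranges are rejected with an
    error naming the offending field. Every applied default is echoed to
    the run log.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigFileError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigFileError(f"top level of {path} must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, str(path))

    cfg = PipelineConfig()
    gabor = dict(raw.get("gabor") or {})
    _reject_unknown(gabor, _GABOR_KEYS, "gabor block")
    gvals = {k: getattr(cfg.gabor, k) for k in _GABOR_KEYS}
    for k, v in gabor.items():
        gvals[k] = _check_range(k, v)
    cfg.gabor = GaborParams(**gvals)

    cdbn = dict(raw.get("cdbn") or {})
    _reject_unknown(cdbn, _CDBN_KEYS, "cdbn block")
    if "layers" in cdbn:
        cfg.layers = tuple(LayerSpec(*row) for row in cdbn["layers"])
    alphas = list(cfg.alphas)
    for i, key in enumerate(("alpha1", "alpha2", "alpha3")):
        if key in cdbn:
            alphas[i] = _check_range(key, cdbn[key])
    cfg.alphas = tuple(alphas)
    for key in ("p1", "p2"):
        if key in cdbn:
            setattr(cfg, key, _check_range(key, cdbn[key]))
    for key in ("epochs", "batch_size", "cd_steps"):
        if key in cdbn:
            setattr(cfg, key, int(cdbn[key]))

    classifier = dict(raw.get("classifier") or {})
    _reject_unknown(classifier, _CLASSIFIER_KEYS, "classifier block")
    if "n_trees" in classifier:
        cfg.n_trees = int(classifier["n_trees"])
    if "test_fraction" in classifier:
        cfg.test_fraction = float(classifier["test_fraction"])
        if not 0.0 < cfg.test_fraction < 1.0:
            raise ConfigFileError(f"test_fraction={cfg.test_fraction} outside (0, 1)")

    search = dict(raw.get("search") or {})
    _reject_unknown(search, _SEARCH_KEYS, "search block")
    if "algorithm" in search:
        cfg.search_algorithm = str(search["algorithm"])
        if cfg.search_algorithm not in ("rcga", "bumda", "umda"):
            raise ConfigFileError(f"unknown search algorithm {cfg.search_algorithm!r}")
    if "population" in search:
        cfg.population = int(search["population"])
    if "generations" in search:
        cfg.generations = int(search["generations"])

    if "seed" in raw:
        cfg.seed = int(raw["seed"])

    validate_dimension_chain(cfg.layers, input_side=32)
    defaults_used = sorted(set(_TOP_KEYS) - set(raw))
    logger.info("config %s loaded; default blocks in effect: %s", path, defaults_used)
    return cfg


def run_pipeline(
    config: PipelineConfig,
    dataset: PatchDataset,
    out_dir: str | Path | None = None,
) -> tuple[EvalReport, CDBNModel, np.ndarray]:
    """Execute preprocess -> train -> extract -> classify end to end.

    Returns the evaluation report, the trained model and the feature
    matrix; with ``out_dir`` set, also writes ``model.json``,
    ``features.csv`` and ``report.json`` there. Each stage runs under a
    seed derived from the master seed and the stage name.
    """
    counts = dataset.class_counts()
    if any(v == 0 for v in counts.values()):
        raise ValueError(f"need at least one patch per class, got {counts}")

    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    filtered = np.stack(
        [apply_gabor(p, config.gabor, source_id=str(i)).data for i, p in enumerate(dataset.patches)]
    )
    timings["preprocess"] = time.perf_counter() - t0
    logger.info("preprocess: %d patches in %.1fs", len(dataset), timings["preprocess"])

    t0 = time.perf_counter()
    model = train_layerwise(filtered, config.cdbn_config(seed=stage_seed(config.seed, "train")))
    timings["train"] = time.perf_counter() - t0
    logger.info("train: %d layers in %.1fs", len(model.layers), timings["train"])

    t0 = time.perf_counter()
    features = extract_features_batch(model, filtered)
    timings["extract"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    split_seed = stage_seed(config.seed, "classify")
    train, test = stratified_split(features, dataset.labels, config.test_fraction, seed=split_seed)
    clf = train_classifier(train, n_trees=config.n_trees, seed=split_seed)
    report = evaluate(clf, test)
    timings["classify"] = time.perf_counter() - t0
    logger.info("classify: macro_f1=%.4f accuracy=%.4f", report.macro_f1, report.accuracy)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        model.save(out_dir / "model.json")
        fdf = pd.DataFrame(features, columns=[f"f{i+1}" for i in range(features.shape[1])])
        fdf.insert(0, "source_id", range(len(dataset)))
        fdf["label"] = dataset.labels
        fdf.to_csv(out_dir / "features.csv", index=False)
        payload = report.to_dict()
        payload["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
        payload["seed"] = config.seed
        (out_dir / "report.json").write_text(json.dumps(payload, indent=2))
    return report, model, features
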