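"""Convolutional deep belief network: greedy stack of CRBMs.

The network is trained layer by layer without labels: the first CRBM learns
on the Gabor-enhanced patches, each deeper CRBM on the binarized pooled
output of the layer below. Inference is a deterministic mean-field pass —
bottom-up activations, probabilistic max pooling, thresholding — and the
patch representation is one value per final-layer feature map (the spatial
maximum of its pooled probabilities), a 256-dimensional vector with the
default architecture:

    32x32x3 --(r=5, pool 2)--> 14x14x24 --(r=5, pool 2)--> 5x5x64
            --(r=4, pool 2)--> 1x1x256

Three layers carry one learning rate each (alpha_1..alpha_3) and the two
intermediate binarization thresholds are p_1, p_2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .crbm import (
    CRBMLayer,
    _bottom_up_batch,
    cd_update,
    prob_max_pool,
    reconstruction_cross_entropy,
    sigmoid,
)

__all__ = [
    "LayerSpec",
    "CDBNConfig",
    "CDBNModel",
    "DEFAULT_LAYER_SPECS",
    "validate_dimension_chain",
    "train_layerwise",
    "forward_pass",
    "extract_features",
    "extract_features_batch",
]

N_FEATURES = 256


@dataclass(frozen=True)
class LayerSpec:
    """Architecture of one CRBM layer: map count, filter side, pooling side."""

    n_maps: int
    filter_side: int
    pool_side: int = 2


#: default three-layer architecture realizing a 256-d feature vector on 32x32 input
DEFAULT_LAYER_SPECS: tuple[LayerSpec, ...] = (
    LayerSpec(n_maps=24, filter_side=5, pool_side=2),
    LayerSpec(n_maps=64, filter_side=5, pool_side=2),
    LayerSpec(n_maps=N_FEATURES, filter_side=4, pool_side=2),
)


class ConfigError(ValueError):
    """Invalid or infeasible CDBN configuration."""


@dataclass
class CDBNConfig:
    """Training configuration for the CRBM stack.

    ``learning_rates`` must contain one rate per layer; ``pool_thresholds``
    one threshold per layer *below the top* (the final layer's pooled
    probabilities are never binarized).
    """

    layers: tuple[LayerSpec, ...] = DEFAULT_LAYER_SPECS
    learning_rates: tuple[float, ...] = (1e-2, 1e-2, 1e-2)
    pool_thresholds: tuple[float, ...] = (0.5, 0.5)
    epochs: int = 5
    batch_size: int = 32
    cd_steps: int = 1
    weight_std: float | None = None    # None = 1/sqrt(fan-in) per layer
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.learning_rates) != len(self.layers):
            raise ConfigError(
                f"{len(self.learning_rates)} learning rates for {len(self.layers)} layers"
            )
        if len(self.pool_thresholds) != max(len(self.layers) - 1, 0):
            raise ConfigError(
                f"expected {len(self.layers) - 1} pooling thresholds, got {len(self.pool_thresholds)}"
            )
        if any(a <= 0 for a in self.learning_rates):
            raise ConfigError("learning rates must be positive")
        if any(not 0.0 <= p <= 1.0 for p in self.pool_thresholds):
            raise ConfigError("pooling thresholds must lie in [0, 1]")
        if self.epochs < 0 or self.batch_size < 1 or self.cd_steps < 1:
            raise ConfigError("epochs >= 0, batch_size >= 1, cd_steps >= 1 required")

    def to_dict(self) -> dict:
        return {
            "layers": [[s.n_maps, s.filter_side, s.pool_side] for s in self.layers],
            "learning_rates": list(self.learning_rates),
            "pool_thresholds": list(self.pool_thresholds),
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "cd_steps": self.cd_steps,
            "weight_std": self.weight_std,
            "seed": self.seed,
        }  # weight_std None means fan-in scaling

    @classmethod
    def from_dict(cls, d: dict) -> "CDBNConfig":
        return cls(
            layers=tuple(LayerSpec(*row) for row in d["layers"]),
            learning_rates=tuple(d["learning_rates"]),
            pool_thresholds=tuple(d["pool_thresholds"]),
            epochs=int(d["epochs"]),
            batch_size=int(d["batch_size"]),
            cd_steps=int(d["cd_steps"]),
            weight_std=None if d["weight_std"] is None else float(d["weight_std"]),
            seed=int(d["seed"]),
        )


def validate_dimension_chain(
    layers: tuple[LayerSpec, ...], input_side: int = 32
) -> list[int]:
    """Check every (valid-conv, pool) pair is realizable; return the side chain.

    Each layer maps side d to floor((d - r + 1) / s); the chain fails if any
    filter outgrows its input or a pooled map vanishes.
    """
    sides = [input_side]
    d = input_side
    for li, spec in enumerate(layers):
        hidden = d - spec.filter_side + 1
        if hidden < 1:
            raise ConfigError(
                f"layer {li + 1}: filter side {spec.filter_side} exceeds its {d}x{d} input"
            )
        d = hidden // spec.pool_side
        if d < 1:
            raise ConfigError(
                f"layer {li + 1}: pooling {spec.pool_side} on a {hidden}x{hidden} map leaves nothing"
            )
        sides.append(d)
    return sides


@dataclass
class CDBNModel:
    """Ordered stack of trained CRBM layers with its config and loss traces.

    ``loss_traces[l][e]`` is layer ``l``'s mean reconstruction cross-entropy
    after ``e`` epochs (index 0 = at initialization).
    """

    layers: list[CRBMLayer]
    config: CDBNConfig
    loss_traces: list[list[float]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "cdbn-lesion/model",
                "version": 1,
                "config": self.config.to_dict(),
                "layers": [lay.to_dict() for lay in self.layers],
                "loss_traces": self.loss_traces,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CDBNModel":
        d = json.loads(text)
        if d.get("format") != "cdbn-lesion/model":
            raise ValueError("not a cdbn-lesion model file")
        return cls(
            layers=[CRBMLayer.from_dict(ld) for ld in d["layers"]],
            config=CDBNConfig.from_dict(d["config"]),
            loss_traces=[list(t) for t in d["loss_traces"]],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "CDBNModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _as_batch(patches) -> np.ndarray:
    """Normalize input to (N, I, J, C) float64 in [0, 1]."""
    if isinstance(patches, np.ndarray) and patches.ndim == 4:
        batch = patches.astype(np.float64, copy=False)
    else:
        arrs = []
        for p in patches:
            a = np.asarray(getattr(p, "data", p), dtype=np.float64)
            if a.ndim == 2:
                a = a[..., None]
            arrs.append(a)
        if not arrs:
            raise ValueError("no patches given")
        if len({a.shape for a in arrs}) != 1:
            raise ValueError("patches must share dimensions")
        batch = np.stack(arrs)
    if batch.min() < -1e-9 or batch.max() > 1 + 1e-9:
        raise ValueError("patch values must lie in [0, 1]; run preprocessing first")
    return batch


def _pooled_batch(layer: CRBMLayer, batch: np.ndarray) -> np.ndarray:
    """Pooled probabilities for a batch: (N, I'/s, J'/s, K)."""
    act = _bottom_up_batch(layer, batch)
    return np.stack([prob_max_pool(a, layer.pool_side) for a in act])


def _train_one_layer(
    layer: CRBMLayer, batch: np.ndarray, config: CDBNConfig, rng: np.random.Generator
) -> tuple[CRBMLayer, list[float]]:
    trace = [reconstruction_cross_entropy(layer, batch)]
    n = batch.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            layer = cd_update(layer, batch[idx], cd_steps=config.cd_steps, rng_seed=rng)
        trace.append(reconstruction_cross_entropy(layer, batch))
    return layer, trace


def train_layerwise(patches, config: CDBNConfig) -> CDBNModel:
    """Greedy unsupervised training of the whole stack.

    Layer 1 trains on the (channel-stacked) patches; each deeper layer on
    the previous layer's pooled probabilities binarized at that layer's
    threshold. A fixed config seed yields an identical model.
    """
    batch = _as_batch(patches)
    validate_dimension_chain(config.layers, input_side=batch.shape[1])
    rng = np.random.default_rng(config.seed)
    layers: list[CRBMLayer] = []
    traces: list[list[float]] = []
    current = batch
    n_layers = len(config.layers)
    for li, spec in enumerate(config.layers):
        threshold = config.pool_thresholds[li] if li < n_layers - 1 else 0.5
        layer = CRBMLayer.initialize(
            spec.n_maps,
            spec.filter_side,
            n_channels=current.shape[3],
            pool_side=spec.pool_side,
            pool_threshold=threshold,
            learning_rate=config.learning_rates[li],
            weight_std=config.weight_std,
            rng=rng,
        )
        layer, trace = _train_one_layer(layer, current, config, rng)
        layers.append(layer)
        traces.append(trace)
        if li < n_layers - 1:
            pooled = _pooled_batch(layer, current)
            current = (pooled >= layer.pool_threshold).astype(np.float64)
    return CDBNModel(layers=layers, config=config, loss_traces=traces)


def forward_pass(model: CDBNModel, patch) -> list[np.ndarray]:
    """Deterministic mean-field pass; returns each layer's pooled maps.

    Intermediate pooled probabilities are binarized (1 iff probability >=
    that layer's threshold) before feeding the next layer; the final
    layer's pooled probabilities are returned unbinarized.
    """
    return [maps[0] for maps in _forward_batch(model, _as_batch([patch]))]


def _forward_batch(model: CDBNModel, batch: np.ndarray) -> list[np.ndarray]:
    outputs = []
    current = batch
    last = len(model.layers) - 1
    for li, layer in enumerate(model.layers):
        pooled = _pooled_batch(layer, current)
        outputs.append(pooled)
        if li < last:
            current = (pooled >= layer.pool_threshold).astype(np.float64)
    return outputs


def extract_features(model: CDBNModel, patch) -> np.ndarray:
    """256-d representation: spatial max of each final-layer pooled map."""
    return extract_features_batch(model, [patch])[0]


def extract_features_batch(model: CDBNModel, patches) -> np.ndarray:
    """Feature matrix (N, 256) for a batch of patches."""
    if model.layers[-1].n_maps != N_FEATURES:
        raise ConfigError(
            f"final layer has {model.layers[-1].n_maps} maps; feature contract requires {N_FEATURES}"
        )
    batch = _as_batch(patches)
    final_pooled = _forward_batch(model, batch)[-1]  # (N, a, b, 256)
    return final_pooled.max(axis=(1, 2))
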