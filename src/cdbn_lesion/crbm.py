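"""Restricted Boltzmann machines: dense oracle model and convolutional RBM.

The dense RBM is the classical bipartite energy model

    E(v, h) = - sum_j b_j v_j - sum_i c_i h_i - sum_ij w_ij h_i v_j

whose conditionals factorize into independent Bernoulli units with sigmoid
activation. The convolutional RBM (CRBM) replaces the dense weight matrix
with K shared r x r filters applied at every spatial location of an image,
so each hidden unit reads one local receptive field:

    E(v, {h_k}) = - sum_k sum_ij h_k(i,j) [ (w_k * v)(i,j) + b_k ]
                  - c sum_ij v(i,j)

with the "valid" convolution (w_k * v)(i,j) = sum_pq w_k(p,q) v(i+p, j+q).
The hidden conditional is sigmoid of the bottom-up filter response plus a
per-map bias; the visible conditional back-projects every hidden unit onto
the r x r patch it reads (the adjoint of the valid convolution, equivalently
a full convolution with the doubly flipped filter) plus a scalar visible
bias.

Probabilistic max pooling aggregates each non-overlapping pooling region of
a feature map into a single unit via a softmax-with-off-state:

    P(pool on) = sum_P exp(a) / (1 + sum_P exp(a))

where ``a`` are the pre-sigmoid bottom-up activations in the region. The
extra 1 in the denominator is the probability that no unit in the region
fires, which makes the pooling a competition rather than a deterministic
max. (Exponentiating the *binary* hidden states instead of their
activations — a literal reading of the printed pooling formula — collapses
the competition to two possible values per unit and is only kept behind the
``literal_binary`` flag for comparison.)

Visible units hold normalized intensities in [0, 1] and are used directly
as mean-field values in the energy and conditionals; Bernoulli sampling of
visibles remains available for Gibbs chains.

Training uses contrastive divergence (CD-k): parameters move along the
difference between data-clamped correlations and correlations after k steps
of alternating Gibbs sampling, batch-averaged. No momentum or weight decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._serialize import decode_array, encode_array

__all__ = [
    "DenseRBM",
    "CRBMLayer",
    "sigmoid",
    "dense_energy",
    "dense_conditionals",
    "crbm_energy",
    "hidden_conditional",
    "visible_conditional",
    "prob_max_pool",
    "gibbs_step",
    "cd_update",
    "flip_filter",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Dense RBM (oracle model)
# ---------------------------------------------------------------------------


@dataclass
class DenseRBM:
    """Fully connected RBM with n visible and m hidden Bernoulli units.

    ``weights`` has shape (n_visible, m_hidden); ``visible_bias`` length n,
    ``hidden_bias`` length m.
    """

    weights: np.ndarray
    visible_bias: np.ndarray
    hidden_bias: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.visible_bias = np.asarray(self.visible_bias, dtype=np.float64)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=np.float64)
        n, m = self.weights.shape
        if self.visible_bias.shape != (n,) or self.hidden_bias.shape != (m,):
            raise ValueError("bias shapes inconsistent with weight matrix")
        for a in (self.weights, self.visible_bias, self.hidden_bias):
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite RBM parameter")


def dense_energy(rbm: DenseRBM, v: np.ndarray, h: np.ndarray) -> float:
    """E(v, h) = -b.v - c.h - v^T W h."""
    v = np.asarray(v, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    n, m = rbm.weights.shape
    if v.shape != (n,) or h.shape != (m,):
        raise ValueError(f"state shapes {v.shape}/{h.shape} do not match RBM ({n}, {m})")
    return float(-rbm.visible_bias @ v - rbm.hidden_bias @ h - v @ rbm.weights @ h)


def dense_conditionals(rbm: DenseRBM, clamped: np.ndarray, side: str = "visible") -> np.ndarray:
    """Bernoulli activation probabilities of the free layer.

    ``side`` names the clamped layer: with ``side="visible"`` the hidden
    probabilities sigmoid(W^T v + c_hidden) are returned; with
    ``side="hidden"`` the visible probabilities sigmoid(W h + b_visible).
    The bias added is always that of the layer being activated.
    """
    clamped = np.asarray(clamped, dtype=np.float64)
    n, m = rbm.weights.shape
    if side == "visible":
        if clamped.shape != (n,):
            raise ValueError(f"visible state length {clamped.shape} != {n}")
        return sigmoid(rbm.weights.T @ clamped + rbm.hidden_bias)
    if side == "hidden":
        if clamped.shape != (m,):
            raise ValueError(f"hidden state length {clamped.shape} != {m}")
        return sigmoid(rbm.weights @ clamped + rbm.visible_bias)
    raise ValueError(f"side must be 'visible' or 'hidden', got {side!r}")


# ---------------------------------------------------------------------------
# Convolutional RBM
# ---------------------------------------------------------------------------


@dataclass
class CRBMLayer:
    """One convolutional RBM layer.

    Attributes
    ----------
    filters
        Array of shape (K, r, r, C): K filters of side r over C input
        channels.
    hidden_bias
        Length-K array, one shared scalar per feature map.
    visible_bias
        Scalar bias shared by every visible unit.
    pool_side
        Side of the non-overlapping pooling regions (default 2).
    pool_threshold
        Binarization threshold applied to pooled probabilities when this
        layer feeds a deeper layer, in [0, 1].
    learning_rate
        CD step size.
    """

    filters: np.ndarray
    hidden_bias: np.ndarray
    visible_bias: float = 0.0
    pool_side: int = 2
    pool_threshold: float = 0.5
    learning_rate: float = 1e-2

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=np.float64)
        if self.filters.ndim == 3:  # (K, r, r) single channel
            self.filters = self.filters[..., None]
        if self.filters.ndim != 4 or self.filters.shape[1] != self.filters.shape[2]:
            raise ValueError(f"filters must be (K, r, r, C), got {self.filters.shape}")
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=np.float64).reshape(-1)
        if self.hidden_bias.shape[0] != self.filters.shape[0]:
            raise ValueError("one hidden bias per feature map required")
        if self.pool_side < 1:
            raise ValueError("pool_side must be >= 1")
        if not 0.0 <= self.pool_threshold <= 1.0:
            raise ValueError("pool_threshold must lie in [0, 1]")
        if not np.all(np.isfinite(self.filters)) or not np.all(np.isfinite(self.hidden_bias)):
            raise ValueError("non-finite CRBM parameter")

    @property
    def n_maps(self) -> int:
        return self.filters.shape[0]

    @property
    def filter_side(self) -> int:
        return self.filters.shape[1]

    @property
    def n_channels(self) -> int:
        return self.filters.shape[3]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "filters": encode_array(self.filters),
            "hidden_bias": encode_array(self.hidden_bias),
            "visible_bias": float(self.visible_bias),
            "pool_side": int(self.pool_side),
            "pool_threshold": float(self.pool_threshold),
            "learning_rate": float(self.learning_rate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CRBMLayer":
        return cls(
            filters=decode_array(d["filters"]),
            hidden_bias=decode_array(d["hidden_bias"]),
            visible_bias=float(d["visible_bias"]),
            pool_side=int(d["pool_side"]),
            pool_threshold=float(d["pool_threshold"]),
            learning_rate=float(d["learning_rate"]),
        )

    @classmethod
    def initialize(
        cls,
        n_maps: int,
        filter_side: int,
        n_channels: int = 1,
        *,
        pool_side: int = 2,
        pool_threshold: float = 0.5,
        learning_rate: float = 1e-2,
        weight_std: float | None = None,
        hidden_bias_init: float | None = None,
        rng: np.random.Generator | int | None = None,
    ) -> "CRBMLayer":
        """Seeded zero-mean Gaussian filters with activation-preserving scales.

        By default the filter std is 1/sqrt(fan-in) (fan-in = r*r*C), so
        bottom-up activations keep O(1) spread regardless of layer width,
        and the hidden bias starts at -log(pool_side**2), which centres the
        pooled on-probability of a zero-input region at 1/2 instead of its
        unbiased value area/(area+1). Pass explicit ``weight_std`` /
        ``hidden_bias_init`` (e.g. 0.01 and 0.0) to override. The visible
        bias starts at zero.
        """
        rng = np.random.default_rng(rng)
        if weight_std is None:
            weight_std = 1.0 / math.sqrt(filter_side * filter_side * n_channels)
        if hidden_bias_init is None:
            hidden_bias_init = -math.log(pool_side * pool_side)
        filters = rng.normal(0.0, weight_std, size=(n_maps, filter_side, filter_side, n_channels))
        return cls(
            filters=filters,
            hidden_bias=np.full(n_maps, hidden_bias_init, dtype=np.float64),
            visible_bias=0.0,
            pool_side=pool_side,
            pool_threshold=pool_threshold,
            learning_rate=learning_rate,
        )


def _as_3d(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if v.ndim == 2:
        v = v[..., None]
    if v.ndim != 3:
        raise ValueError(f"visible map must be 2-D or (H, W, C), got shape {v.shape}")
    return v


def _bottom_up_batch(layer: CRBMLayer, v: np.ndarray) -> np.ndarray:
    """Pre-sigmoid hidden activations for a batch.

    ``v`` has shape (N, I, J, C); returns (N, I', J', K) with
    I' = I - r + 1, J' = J - r + 1.
    """
    r = layer.filter_side
    if v.shape[1] < r or v.shape[2] < r:
        raise ValueError(f"visible map {v.shape[1:3]} smaller than filter side {r}")
    if v.shape[3] != layer.n_channels:
        raise ValueError(f"visible channels {v.shape[3]} != filter channels {layer.n_channels}")
    # windows: (N, I', J', C, r, r)
    windows = sliding_window_view(v, (r, r), axis=(1, 2))
    act = np.einsum("nijcpq,kpqc->nijk", windows, layer.filters, optimize=True)
    return act + layer.hidden_bias


def bottom_up(layer: CRBMLayer, v: np.ndarray) -> np.ndarray:
    """Pre-sigmoid activations (w_k * v) + b_k, shape (I', J', K)."""
    return _bottom_up_batch(layer, _as_3d(v)[None])[0]


def hidden_conditional(layer: CRBMLayer, v: np.ndarray) -> np.ndarray:
    """P(h_k(i,j) = 1 | v) = sigmoid((w_k * v)(i,j) + b_k), shape (I',J',K)."""
    return sigmoid(bottom_up(layer, v))


def flip_filter(w: np.ndarray) -> np.ndarray:
    """Flip a filter along both spatial dimensions (first two axes)."""
    return w[::-1, ::-1]


def _top_down_batch(layer: CRBMLayer, h: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Back-projected visible field for a batch of hidden maps.

    ``h`` has shape (N, I', J', K); returns (N, I, J, C). Hidden unit
    (i', j') of map k adds h * w_k onto the visible patch
    [i', i'+r) x [j', j'+r) — the adjoint of the valid convolution,
    equal to the zero-padded full convolution with the flipped filter.
    """
    r = layer.filter_side
    n, ih, jh, k = h.shape
    out = np.zeros((n, out_shape[0], out_shape[1], layer.n_channels))
    for p in range(r):
        for q in range(r):
            # (N, I', J', K) @ (K, C) -> (N, I', J', C)
            out[:, p : p + ih, q : q + jh, :] += h @ layer.filters[:, p, q, :]
    return out


def visible_conditional(layer: CRBMLayer, h: np.ndarray, visible_shape: tuple[int, int]) -> np.ndarray:
    """P(v(i,j) = 1 | {h_k}) = sigmoid(sum_k (w~_k * h_k)(i,j) + c).

    ``visible_shape`` is the (I, J) of the visible layer; output has shape
    (I, J, C) (squeeze channel for single-channel layers yourself if
    wanted).
    """
    h = np.asarray(h, dtype=np.float64)
    if h.ndim == 2:
        h = h[..., None]
    if h.ndim != 3 or h.shape[2] != layer.n_maps:
        raise ValueError(f"hidden maps must be (I', J', K={layer.n_maps}), got {h.shape}")
    r = layer.filter_side
    exp = (visible_shape[0] - r + 1, visible_shape[1] - r + 1)
    if h.shape[:2] != exp:
        raise ValueError(f"hidden map dims {h.shape[:2]} incompatible with visible {visible_shape}")
    field_sum = _top_down_batch(layer, h[None], visible_shape)[0]
    return sigmoid(field_sum + layer.visible_bias)


def crbm_energy(layer: CRBMLayer, v: np.ndarray, h: np.ndarray) -> float:
    """Joint energy of a visible map and its hidden feature maps."""
    v = _as_3d(v)
    h = np.asarray(h, dtype=np.float64)
    if h.ndim == 2:
        h = h[..., None]
    act = bottom_up(layer, v)  # includes b_k
    if h.shape != act.shape:
        raise ValueError(f"hidden shape {h.shape} does not match activation shape {act.shape}")
    return float(-(h * act).sum() - layer.visible_bias * v.sum())


# ---------------------------------------------------------------------------
# Probabilistic max pooling
# ---------------------------------------------------------------------------


def prob_max_pool(activation: np.ndarray, region_side: int) -> np.ndarray:
    """Pool pre-sigmoid activations with an explicit off state.

    For each non-overlapping ``region_side`` x ``region_side`` block the
    pooled unit's on-probability is sum(exp(a)) / (1 + sum(exp(a))),
    evaluated with a max-shift so large activations cannot overflow while
    the ratio stays exact. If a map dimension is not divisible by
    ``region_side`` the trailing rows/columns are cropped.

    Accepts a 2-D map or an (I, J, K) stack; pools each map independently.
    """
    if region_side < 1:
        raise ValueError("region_side must be >= 1")
    a = np.asarray(activation, dtype=np.float64)
    squeeze = a.ndim == 2
    if squeeze:
        a = a[..., None]
    if a.ndim != 3:
        raise ValueError(f"activation must be 2-D or 3-D, got shape {a.shape}")
    s = region_side
    ih = (a.shape[0] // s) * s
    jh = (a.shape[1] // s) * s
    if ih == 0 or jh == 0:
        raise ValueError(f"map {a.shape[:2]} smaller than pooling region {s}")
    a = a[:ih, :jh]
    blocks = a.reshape(ih // s, s, jh // s, s, a.shape[2]).transpose(0, 2, 4, 1, 3)
    blocks = blocks.reshape(ih // s, jh // s, a.shape[2], s * s)
    # shift by max(block max, 0) so both numerator and the off-state term
    # exp(-m) stay representable; the ratio is algebraically unchanged
    m = np.maximum(blocks.max(axis=-1), 0.0)
    num = np.exp(blocks - m[..., None]).sum(axis=-1)
    pooled = num / (np.exp(-m) + num)
    # finite activations give probabilities strictly inside (0, 1); keep the
    # float result inside the open interval as well
    pooled = np.clip(pooled, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    return pooled[..., 0] if squeeze else pooled


def prob_max_pool_binary(h_sample: np.ndarray, region_side: int) -> np.ndarray:
    """Literal variant pooling exp of binary hidden states (diagnostic only).

    Applies the same formula to 0/1 states instead of activations; with
    binary inputs the pooled value can only take region_side**2 + 1 distinct
    values, so the competition is nearly constant — kept for comparison with
    the activation-based pooling used everywhere else.
    """
    return prob_max_pool(np.asarray(h_sample, dtype=np.float64), region_side)


# ---------------------------------------------------------------------------
# Gibbs sampling and contrastive divergence
# ---------------------------------------------------------------------------


def gibbs_step(
    layer: CRBMLayer, v: np.ndarray, rng_seed: np.random.Generator | int
) -> tuple[np.ndarray, np.ndarray]:
    """One alternating Gibbs half-step from a visible configuration.

    Samples binary hidden maps from their conditional given ``v`` and
    returns ``(h_sample, v_reconstruction_probabilities)``. Identical seeds
    give bitwise-identical outputs.
    """
    rng = np.random.default_rng(rng_seed)
    v = _as_3d(v)
    probs = hidden_conditional(layer, v)
    h_sample = (rng.random(probs.shape) < probs).astype(np.float64)
    v_recon = visible_conditional(layer, h_sample, v.shape[:2])
    return h_sample, v_recon


def _correlate_batch(v: np.ndarray, h: np.ndarray, r: int) -> np.ndarray:
    """Batch-mean of the positive/negative statistic sum_ij h_k(i,j) v(i+p, j+q, c).

    Returns an array of filter shape (K, r, r, C).
    """
    windows = sliding_window_view(v, (r, r), axis=(1, 2))  # (N, I', J', C, r, r)
    grad = np.einsum("nijk,nijcpq->kpqc", h, windows, optimize=True)
    return grad / v.shape[0]


def cd_update(
    layer: CRBMLayer,
    v_batch: np.ndarray | list[np.ndarray],
    cd_steps: int = 1,
    rng_seed: np.random.Generator | int = 0,
) -> CRBMLayer:
    """One contrastive-divergence parameter update on a batch.

    Positive statistics correlate the data-clamped visibles with their
    hidden probabilities; negative statistics use the mean-field visible
    reconstruction after ``cd_steps`` Gibbs steps (hidden states sampled,
    visibles kept as probabilities). Updates are batch-averaged and scaled
    by the layer's learning rate. Returns a new layer; the input layer is
    not modified.
    """
    if cd_steps < 1:
        raise ValueError("cd_steps must be >= 1")
    rng = np.random.default_rng(rng_seed)
    if isinstance(v_batch, list):
        v_batch = np.stack([_as_3d(v) for v in v_batch])
    else:
        v_batch = np.asarray(v_batch, dtype=np.float64)
        if v_batch.ndim == 3:
            v_batch = v_batch[..., None]
    if v_batch.ndim != 4:
        raise ValueError(f"batch must be (N, I, J, C), got shape {v_batch.shape}")
    if v_batch.shape[0] == 0:
        raise ValueError("empty batch")

    r = layer.filter_side
    vis_shape = v_batch.shape[1:3]

    h0_probs = sigmoid(_bottom_up_batch(layer, v_batch))
    v_neg = v_batch
    h_probs = h0_probs
    for _ in range(cd_steps):
        h_sample = (rng.random(h_probs.shape) < h_probs).astype(np.float64)
        v_neg = sigmoid(_top_down_batch(layer, h_sample, vis_shape) + layer.visible_bias)
        h_probs = sigmoid(_bottom_up_batch(layer, v_neg))

    pos_w = _correlate_batch(v_batch, h0_probs, r)
    neg_w = _correlate_batch(v_neg, h_probs, r)
    d_w = pos_w - neg_w
    d_b = (h0_probs.sum(axis=(1, 2)) - h_probs.sum(axis=(1, 2))).mean(axis=0)
    d_c = float((v_batch.sum(axis=(1, 2, 3)) - v_neg.sum(axis=(1, 2, 3))).mean())

    alpha = layer.learning_rate
    new_filters = layer.filters + alpha * d_w
    new_hbias = layer.hidden_bias + alpha * d_b
    new_vbias = layer.visible_bias + alpha * d_c
    if not (np.all(np.isfinite(new_filters)) and np.all(np.isfinite(new_hbias)) and np.isfinite(new_vbias)):
        raise FloatingPointError(
            "contrastive-divergence update overflowed: non-finite parameters "
            f"(|dW|max={np.abs(d_w).max():.3g}, alpha={alpha:.3g})"
        )
    return replace(layer, filters=new_filters, hidden_bias=new_hbias, visible_bias=new_vbias)


def reconstruction_cross_entropy(layer: CRBMLayer, v_batch: np.ndarray) -> float:
    """Mean per-unit Bernoulli cross-entropy of the mean-field reconstruction.

    The visibles are reconstructed from the hidden *probabilities* (no
    sampling), so the value is deterministic given the layer and batch.
    """
    v_batch = np.asarray(v_batch, dtype=np.float64)
    if v_batch.ndim == 3:
        v_batch = v_batch[..., None]
    h_probs = sigmoid(_bottom_up_batch(layer, v_batch))
    v_rec = sigmoid(_top_down_batch(layer, h_probs, v_batch.shape[1:3]) + layer.visible_bias)
    eps = 1e-12
    v_rec = np.clip(v_rec, eps, 1.0 - eps)
    ce = -(v_batch * np.log(v_rec) + (1.0 - v_batch) * np.log(1.0 - v_rec))
    return float(ce.mean())
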