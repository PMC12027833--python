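"""Gabor-filter feature enhancement for retinal patches.

A single real-valued 2-D Gabor kernel — an oriented cosine carrier under an
anisotropic Gaussian envelope — is built from six parameters and convolved
independently with each color channel of a patch. The filtered channels are
then min–max rescaled to [0, 1] so they can feed a Bernoulli-visible CRBM.

The six parameters and their admissible ranges (the same ranges the
evolutionary search explores):

=========  =============================  ==============
name       meaning                        range
=========  =============================  ==============
sigma      Gaussian envelope scale        [100, 200]
theta      carrier orientation (rad)      [0, pi]
lam        carrier wavelength (px)        [8, 16]
psi        carrier phase offset (rad)     [0, 2*pi]
gamma      spatial aspect ratio           [0.5, 1.0]
k          kernel-side control (px)       [45, 180]
=========  =============================  ==============

``k`` is real-valued in the search space; the realized kernel side is
``round(k)`` forced odd (incremented by one if even).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "GaborParams",
    "FilteredPatch",
    "GABOR_BOUNDS",
    "build_gabor_kernel",
    "apply_gabor",
]

#: lower/upper bound per Gabor parameter, in canonical order
GABOR_BOUNDS: dict[str, tuple[float, float]] = {
    "sigma": (100.0, 200.0),
    "theta": (0.0, math.pi),
    "lam": (8.0, 16.0),
    "psi": (0.0, 2.0 * math.pi),
    "gamma": (0.5, 1.0),
    "k": (45.0, 180.0),
}


class GaborConfigError(ValueError):
    """Raised for non-finite or out-of-range Gabor parameters."""


@dataclass(frozen=True)
class GaborParams:
    """Parameters of a single real 2-D Gabor filter.

    Values are validated to be finite on construction; :meth:`clipped`
    returns a copy with every field clipped into its search range.
    """

    sigma: float
    theta: float
    lam: float
    psi: float
    gamma: float
    k: float

    def __post_init__(self) -> None:
        for name in GABOR_BOUNDS:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise GaborConfigError(f"Gabor parameter {name!r} is not finite: {value!r}")
        if self.lam <= 0:
            raise GaborConfigError(f"wavelength must be positive, got {self.lam}")
        if self.sigma <= 0:
            raise GaborConfigError(f"sigma must be positive, got {self.sigma}")

    def clipped(self) -> "GaborParams":
        """Return a copy with every field clipped into its printed range."""
        vals = {n: float(np.clip(getattr(self, n), lo, hi)) for n, (lo, hi) in GABOR_BOUNDS.items()}
        return GaborParams(**vals)

    @property
    def kernel_side(self) -> int:
        """Realized odd kernel side length derived from ``k``."""
        side = int(round(self.k))
        if side % 2 == 0:
            side += 1
        if side < 1:
            raise GaborConfigError(f"kernel-size control k={self.k} yields side {side}")
        return side


@dataclass(frozen=True)
class FilteredPatch:
    """A Gabor-filtered patch: 3-channel float image with values in [0, 1]."""

    data: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3 or d.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 data, got shape {d.shape}")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("filtered patch values must lie in [0, 1]")


def build_gabor_kernel(params: GaborParams) -> np.ndarray:
    """Evaluate the real 2-D Gabor function on an odd square grid.

    g(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) * cos(2 pi x' / lam + psi)

    with rotated coordinates x' = x cos(theta) + y sin(theta),
    y' = -x sin(theta) + y cos(theta), evaluated at integer offsets centred
    on the kernel middle. The side length comes from ``params.kernel_side``.
    """
    side = params.kernel_side
    half = side // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    xr = x * math.cos(params.theta) + y * math.sin(params.theta)
    yr = -x * math.sin(params.theta) + y * math.cos(params.theta)
    envelope = np.exp(-(xr**2 + params.gamma**2 * yr**2) / (2.0 * params.sigma**2))
    carrier = np.cos(2.0 * math.pi * xr / params.lam + params.psi)
    return envelope * carrier


def _convolve_reflect(channel: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True 2-D convolution with same-size output and reflective padding.

    Padding is half-sample symmetric (the edge pixel is repeated), which
    keeps the 32x32 patch geometry even for kernels wider than the patch.
    """
    half = kernel.shape[0] // 2
    padded = np.pad(channel, half, mode="symmetric")
    return signal.convolve(padded, kernel, mode="valid")


def apply_gabor(
    patch: np.ndarray,
    params: GaborParams,
    *,
    source_id: str = "",
    rescale: bool = True,
) -> FilteredPatch | np.ndarray:
    """Convolve each color channel with the Gabor kernel.

    Parameters
    ----------
    patch
        H x W x 3 array (any real dtype; 8-bit images are used as-is).
    params
        Filter parameters.
    source_id
        Identifier carried through to the :class:`FilteredPatch`.
    rescale
        When True (default) each output channel is min–max rescaled to
        [0, 1]; a constant channel maps to all zeros. When False the raw
        convolution responses are returned as a plain array (used by the
        linearity tests and diagnostics).
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 patch, got shape {patch.shape}")
    if patch.shape[0] < 2 or patch.shape[1] < 2:
        raise ValueError(f"patch too small to filter: {patch.shape}")
    if not np.all(np.isfinite(patch)):
        raise ValueError("patch contains non-finite values")

    kernel = build_gabor_kernel(params)
    out = np.empty_like(patch)
    for c in range(3):
        out[:, :, c] = _convolve_reflect(patch[:, :, c], kernel)
    if not rescale:
        return out

    for c in range(3):
        lo, hi = out[:, :, c].min(), out[:, :, c].max()
        if hi - lo < 1e-12:
            out[:, :, c] = 0.0
        else:
            out[:, :, c] = (out[:, :, c] - lo) / (hi - lo)
    return FilteredPatch(data=out, source_id=source_id)
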