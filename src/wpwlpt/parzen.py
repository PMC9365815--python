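"""Parzen-window machinery on the gray-value axis.

A gray image is reduced to its level sets: for each gray level l the set
of pixels with value l, of cardinality C_l.  Each populated level carries a
Gaussian kernel centred at l whose width follows the classical
Parzen-window rule

    sigma_l = c / sqrt(C_l),

optionally floored at ``sigma_min`` so that heavily populated levels do not
degenerate into near-delta spikes.  Kernels are fully normalized densities
(the 1/V_n volume factor is folded into the kernel), so any convex
combination of them integrates to one.

Two densities are built from these pieces:

* the class-conditional density of one level, p(g | level l) — all C_l
  samples of the level share the same gray value, so the Parzen average
  collapses to a single kernel evaluation;
* a weighted mixture over levels, sum_i a_i phi(g; g_i, sigma_i), whose
  weights a_i are chosen downstream by linear programming (`wpwlpt.lp`)
  rather than by the histogram.

The plain count-weighted mixture (a_i = C_i / N) is also provided; it is
the ordinary Parzen density estimate of the gray-value distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import L

__all__ = [
    "KernelSpec",
    "LevelSets",
    "DensityModel",
    "level_sets",
    "window_width",
    "kernel_eval",
    "conditional_density",
    "mixture_density",
    "parzen_density",
]

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class KernelSpec:
    """Width rule of the per-level kernels.

    c : dimensionless constant of the window-width rule h_n = c / sqrt(n).
    sigma_min : floor on widths, gray-level units; 0 disables the floor.
    dim : kernel dimensionality d (1 on the gray-value axis).
    """

    c: float = 1.0
    sigma_min: float = 0.5
    dim: int = 1

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.sigma_min < 0:
            raise ValueError("sigma_min must be >= 0")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")


@dataclass(frozen=True)
class LevelSets:
    """Per-gray-level pixel counts of one image.

    counts[l] = C_l for l in 0..L-1; total = sum C_l = number of pixels.
    """

    counts: np.ndarray
    total: int

    @property
    def present_levels(self) -> np.ndarray:
        """Sorted gray levels with C_l > 0."""
        return np.flatnonzero(self.counts)


@dataclass(frozen=True)
class DensityModel:
    """A weighted kernel mixture sum_i a_i phi(g; centers_i, widths_i).

    weights lie on the probability simplex; rho is the coverage level the
    mixture guarantees at every centre (see `wpwlpt.lp`); support is the
    index set of strictly positive weights.
    """

    centers: np.ndarray
    widths: np.ndarray
    weights: np.ndarray
    rho: float
    dim: int = 1
    support_tol: float = 1e-9

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=np.float64)
        widths = np.asarray(self.widths, dtype=np.float64)
        weights = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "widths", widths)
        object.__setattr__(self, "weights", weights)
        if not (centers.shape == widths.shape == weights.shape):
            raise ValueError("centers, widths, weights must have equal shapes")
        if centers.size == 0:
            raise ValueError("model must have at least one centre")
        if np.any(widths <= 0):
            raise ValueError("widths must be > 0")
        if np.any(weights < -1e-12):
            raise ValueError("weights must be >= 0")
        if abs(float(weights.sum()) - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")
        peak_max = kernel_eval(0.0, 0.0, float(widths.min()), self.dim)
        if not (-1e-12 <= self.rho <= peak_max * (1 + 1e-9)):
            raise ValueError("rho outside its admissible range [0, peak_max]")

    @property
    def support(self) -> np.ndarray:
        """Indices i with a_i above the support tolerance."""
        return np.flatnonzero(self.weights > self.support_tol)


def level_sets(image: np.ndarray) -> LevelSets:
    """Histogram bookkeeping: C_l per gray level and the total pixel count."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image is empty")
    if image.min() < 0 or image.max() > L - 1:
        raise ValueError(f"gray values must lie in [0, {L - 1}]")
    counts = np.bincount(image.ravel().astype(np.int64), minlength=L)
    return LevelSets(counts=counts, total=int(image.size))


def window_width(count: int, spec: KernelSpec = KernelSpec()) -> float:
    """Data-dependent width sigma_l = max(c / sqrt(C_l), sigma_min)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    return max(spec.c / np.sqrt(float(count)), spec.sigma_min)


def level_widths(levels: LevelSets, spec: KernelSpec = KernelSpec()) -> np.ndarray:
    """Widths of every populated level, in present_levels order."""
    counts = levels.counts[levels.present_levels].astype(np.float64)
    return np.maximum(spec.c / np.sqrt(counts), spec.sigma_min)


def kernel_eval(g, center, sigma: float, dim: int = 1):
    """Normalized isotropic Gaussian kernel on the gray axis.

    phi(g; center, sigma) = (2 pi)^(-d/2) sigma^(-d) exp(-|g-center|^2 / (2 sigma^2)),
    symmetric in (g, center); the peak value is (sqrt(2 pi) sigma)^(-d).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    g = np.asarray(g, dtype=np.float64)
    center = np.asarray(center, dtype=np.float64)
    norm = (_SQRT_2PI * sigma) ** (-dim)
    out = norm * np.exp(-((g - center) ** 2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def conditional_density(
    g, level: int, levels: LevelSets, spec: KernelSpec = KernelSpec()
):
    """Parzen estimate of p(g | level l).

    On the gray axis all C_l samples of the level sit at g = l, so the
    average of C_l identical kernels is one kernel evaluation with the
    level's own width.
    """
    if levels.counts[level] == 0:
        raise KeyError(f"gray level {level} not present in the image")
    sigma = window_width(int(levels.counts[level]), spec)
    return kernel_eval(g, level, sigma, spec.dim)


def mixture_density(g, model: DensityModel):
    """Evaluate the weighted mixture sum_{i in support} a_i phi(g; g_i, sigma_i)."""
    g = np.asarray(g, dtype=np.float64)
    idx = model.support
    out = np.zeros(g.shape, dtype=np.float64)
    for i in idx:
        out += model.weights[i] * kernel_eval(
            g, model.centers[i], float(model.widths[i]), model.dim
        )
    return float(out) if out.ndim == 0 else out


def parzen_density(g, levels: LevelSets, spec: KernelSpec = KernelSpec()):
    """Classical Parzen estimate of the gray-value density.

    Count-weighted mixture sum_l (C_l / N) phi(g; l, sigma_l) — the histogram
    smoothed by the per-level kernels.
    """
    present = levels.present_levels
    widths = level_widths(levels, spec)
    weights = levels.counts[present] / float(levels.total)
    model = DensityModel(
        centers=present.astype(np.float64),
        widths=widths,
        weights=weights,
        rho=0.0,
        dim=spec.dim,
    )
    return mixture_density(g, model)
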