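"""Bi-level thresholding: the weighted Parzen-window LP method and baselines.

The WPWLPT pipeline: level sets -> per-level kernel widths -> maximin
coverage LP -> fitted mixture p_hat with guaranteed coverage rho* ->
boundary extraction -> threshold t -> binary mask.  A pixel with value
<= t maps to 0 (background), > t maps to 1 (foreground).

Boundary extraction.  By construction every populated gray level satisfies
p_hat >= rho*, so the sub-rho* region of the gray axis — the outside of the
distribution's boundary — lives at unpopulated levels.  When the histogram
has a genuine hole between its two classes (well-separated modes), the
threshold is the midpoint of the widest/deepest sub-rho* gap whose two
sides both carry real pixel mass.  When the modes overlap and every level
in between is populated (no admissible gap), the coverage constraints are
equalized at the optimum and the LP trace carries no interior minimum; the
boundary is then placed at the valley of the count-weighted Parzen density
of the gray values, smoothed at Silverman's bandwidth so the valley
position is stable under resampling of the noise.

Baselines: Otsu's between-class variance criterion and the Kapur--Sahoo--
Wong (KSW) maximum-entropy criterion, both as exact exhaustive sweeps over
all candidate thresholds.  All argmax/argmin sweeps break ties toward the
smallest gray level, making every method deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from . import lp as lp_mod
from .parzen import DensityModel, KernelSpec, LevelSets, level_sets, level_widths, mixture_density
from .synthetic import L

__all__ = [
    "DegenerateImageError",
    "ThresholdResult",
    "binarize",
    "classify_levels",
    "extract_threshold",
    "wpwlpt_threshold",
    "otsu_threshold",
    "ksw_threshold",
]

# a sub-rho* gap only counts as the class boundary if each side of it
# holds at least this fraction of the pixels (rejects gaps caused by a
# few stray tail pixels)
GAP_MIN_SIDE_MASS = 0.01


class DegenerateImageError(ValueError):
    """Raised for images with fewer than two distinct gray levels."""


@dataclass(frozen=True)
class ThresholdResult:
    """Threshold, induced gray-level partition and binary mask.

    class_B holds the gray levels <= t (mapped to 0), class_O the levels
    > t (mapped to 1); together they partition the populated levels.
    rho / density_trace / model / solution are diagnostics of the LP
    method and are None for the baselines.
    """

    threshold: int
    class_O: np.ndarray
    class_B: np.ndarray
    mask: np.ndarray
    method: str
    rho: float | None = None
    density_trace: np.ndarray | None = None  # p_hat on the integer gray grid
    model: DensityModel | None = None
    solution: lp_mod.LPSolution | None = None


def binarize(image: np.ndarray, t: int) -> np.ndarray:
    """Per-pixel rule: value <= t -> 0, value > t -> 1 (uint8 mask)."""
    if not (0 <= t <= L - 2):
        raise ValueError(f"threshold {t} outside [0, {L - 2}]")
    image = np.asarray(image)
    return (image > t).astype(np.uint8)


def _partition(levels: LevelSets, t: int) -> tuple[np.ndarray, np.ndarray]:
    present = levels.present_levels
    return present[present > t], present[present <= t]


def _runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers, as inclusive (start, end) pairs."""
    if values.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(values) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [values.size - 1]])
    return [(int(values[s]), int(values[e])) for s, e in zip(starts, ends)]


def silverman_bandwidth(levels: LevelSets) -> float:
    """Silverman's rule-of-thumb bandwidth of the pixel gray values.

    h = 0.9 min(sigma, IQR / 1.34) N^(-1/5) over the whole pixel
    population, floored at one gray level.
    """
    counts = levels.counts.astype(np.float64)
    n = float(levels.total)
    grays = np.arange(counts.size, dtype=np.float64)
    p = counts / n
    mean = float(p @ grays)
    std = float(np.sqrt(p @ (grays - mean) ** 2))
    cdf = np.cumsum(p)
    q1 = float(np.searchsorted(cdf, 0.25))
    q3 = float(np.searchsorted(cdf, 0.75))
    spread = min(std, (q3 - q1) / 1.34) if q3 > q1 else std
    return max(0.9 * spread * n ** (-0.2), 1.0)


def _valley_threshold(levels: LevelSets) -> int:
    """Valley of the Parzen-smoothed gray-value histogram.

    The count histogram is convolved with a Gaussian at Silverman's
    bandwidth and the threshold is the argmin between the two highest
    interior modes of the smoothed curve (ties break toward the smallest
    level).  Restricting the search to the inter-mode interval keeps the
    valley away from the low-density tails, which always lie below the
    true class valley; modes sitting exactly on the range boundary are
    clipping spikes, not distribution modes, and cannot anchor the
    interval.  If the smoothed histogram is unimodal there is no valley
    to find and the between-class-variance optimum is used instead.
    """
    present = levels.present_levels
    g_min, g_max = int(present[0]), int(present[-1])
    if g_max - g_min < 2:
        return g_min
    counts = levels.counts.astype(np.float64)
    # Saturated pixels pile up in the extreme bins (gray 0 and L-1); those
    # spikes are range artifacts, not distribution modes, and would
    # otherwise spawn spurious peaks next to the boundary.  For the mode
    # analysis the extreme bins are replaced by their inner neighbours.
    counts[0] = counts[1]
    counts[-1] = counts[-2]
    smoothed = gaussian_filter1d(
        counts, sigma=silverman_bandwidth(levels), mode="constant"
    )
    peaks, props = find_peaks(smoothed, prominence=0.0)
    if peaks.size < 2:
        return otsu_from_counts(levels.counts)
    top_two = np.sort(peaks[np.argsort(props["prominences"])[-2:]])
    lo, hi = int(top_two[0]), int(top_two[1])
    between = np.arange(lo + 1, hi)
    if between.size == 0:
        return lo
    return int(between[np.argmin(smoothed[between])])


def extract_threshold(
    trace: np.ndarray,
    rho: float,
    levels: LevelSets,
    *,
    min_side_mass: float = GAP_MIN_SIDE_MASS,
    rel_tol: float = 1e-6,
) -> int:
    """Place the threshold from the fitted trace and coverage level rho*.

    ``trace`` is p_hat on the integer grid 0..L-1.  Candidate boundaries
    are the maximal runs of interior integers with p_hat < rho* whose two
    sides each carry at least ``min_side_mass`` of the pixels; among them
    the run with the smallest mean p_hat wins (ties toward the lower run)
    and t is the floor of its midpoint.  Without an admissible run the
    Parzen-valley rule decides.  The result always satisfies
    g_min <= t < g_max over the populated levels.
    """
    present = levels.present_levels
    if present.size < 2:
        raise DegenerateImageError("threshold undefined for a single gray level")
    g_min, g_max = int(present[0]), int(present[-1])
    interior = np.arange(g_min + 1, g_max)
    if interior.size == 0:
        return g_min
    sub = interior[trace[interior] < rho * (1.0 - rel_tol)]
    total = float(levels.total)
    cum = np.cumsum(levels.counts)
    best: tuple[float, int] | None = None
    best_run: tuple[int, int] | None = None
    for start, end in _runs(sub):
        mass_below = cum[start - 1] / total
        mass_above = 1.0 - cum[end] / total
        if mass_below < min_side_mass or mass_above < min_side_mass:
            continue
        mean_p = float(trace[start : end + 1].mean())
        key = (mean_p, start)
        if best is None or key < best:
            best = key
            best_run = (start, end)
    if best_run is not None:
        return int((best_run[0] + best_run[1]) // 2)
    return _valley_threshold(levels)


def classify_levels(
    trace: np.ndarray, rho: float, levels: LevelSets
) -> tuple[np.ndarray, np.ndarray]:
    """Split the populated gray levels into (class_O, class_B) at the boundary.

    Levels above the extracted threshold form class_O, the rest class_B;
    the two classes partition the populated levels exactly.
    """
    t = extract_threshold(trace, rho, levels)
    return _partition(levels, t)


def wpwlpt_threshold(
    image: np.ndarray,
    kernel_spec: KernelSpec = KernelSpec(),
    *,
    lp_tol: float = 1e-9,
) -> ThresholdResult:
    """Threshold an image with the weighted Parzen-window LP method."""
    levels = level_sets(image)
    present = levels.present_levels
    if present.size < 2:
        raise DegenerateImageError("image has fewer than two distinct gray levels")
    widths = level_widths(levels, kernel_spec)
    program = lp_mod.build_lp(present, widths, kernel_spec)
    sol = lp_mod.solve_simplex(program, tol=lp_tol)
    if sol.status != "optimal":
        raise RuntimeError(f"LP solve did not reach optimality: {sol.status}")
    model = DensityModel(
        centers=present.astype(np.float64),
        widths=widths,
        weights=sol.weights / sol.weights.sum(),
        rho=sol.rho,
        dim=kernel_spec.dim,
    )
    trace = mixture_density(np.arange(L, dtype=np.float64), model)
    t = extract_threshold(trace, sol.rho, levels)
    class_O, class_B = _partition(levels, t)
    return ThresholdResult(
        threshold=t,
        class_O=class_O,
        class_B=class_B,
        mask=binarize(image, t),
        method="wpwlpt",
        rho=sol.rho,
        density_trace=trace,
        model=model,
        solution=sol,
    )


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def _histogram(image: np.ndarray) -> np.ndarray:
    levels = level_sets(image)
    if levels.present_levels.size < 2:
        raise DegenerateImageError("image has fewer than two distinct gray levels")
    return levels.counts


def otsu_from_counts(counts: np.ndarray) -> int:
    """Exhaustive Otsu sweep on a histogram: argmax_t w0 w1 (mu0 - mu1)^2."""
    p = counts.astype(np.float64) / counts.sum()
    grays = np.arange(p.size, dtype=np.float64)
    w0 = np.cumsum(p)[:-1]  # mass of class {0..t}, t = 0..L-2
    w1 = 1.0 - w0
    m0 = np.cumsum(p * grays)[:-1]
    mu_total = float((p * grays).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, m0 / w0, 0.0)
        mu1 = np.where(w1 > 0, (mu_total - m0) / w1, 0.0)
    objective = w0 * w1 * (mu0 - mu1) ** 2
    return int(np.argmax(objective))  # ties -> smallest t


def ksw_from_counts(counts: np.ndarray) -> int:
    """Exhaustive Kapur maximum-entropy sweep: argmax_t H_B(t) + H_O(t).

    H_B is the Shannon entropy of the class {0..t} histogram renormalized
    to a distribution, H_O of the complement; empty bins contribute zero
    via the 0 log 0 = 0 convention.  Candidate thresholds are those that
    leave both classes populated (t between the extreme populated levels),
    so the criterion never selects a degenerate one-class split.
    """
    p = counts.astype(np.float64) / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    P = np.cumsum(p)[:-1]
    S = np.cumsum(plogp)[:-1]
    S_total = float(plogp.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        h_b = np.where(P > 0, np.log(P) - S / P, 0.0)
        Q = 1.0 - P
        h_o = np.where(Q > 0, np.log(Q) - (S_total - S) / Q, 0.0)
    objective = h_b + h_o
    valid = np.flatnonzero((P > 0) & (Q > 0))
    return int(valid[np.argmax(objective[valid])])  # ties -> smallest t


def _baseline_result(image: np.ndarray, t: int, method: str) -> ThresholdResult:
    levels = level_sets(image)
    class_O, class_B = _partition(levels, t)
    return ThresholdResult(
        threshold=t,
        class_O=class_O,
        class_B=class_B,
        mask=binarize(image, t),
        method=method,
    )


def otsu_threshold(image: np.ndarray) -> ThresholdResult:
    """Otsu's method: maximize the between-class variance of the histogram."""
    counts = _histogram(image)
    return _baseline_result(image, otsu_from_counts(counts), "otsu")


def ksw_threshold(image: np.ndarray) -> ThresholdResult:
    """Kapur/KSW method: maximize the summed class entropies of the histogram."""
    counts = _histogram(image)
    return _baseline_result(image, ksw_from_counts(counts), "ksw")
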