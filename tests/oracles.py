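"""Independent reference computations used only by the tests.

Everything here is implemented from first principles (loops, enumeration,
published formulas) and shares no code with the package, so agreement
between the two routes is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog
from scipy.signal import convolve2d


# ---------------------------------------------------------------------------
# histogram / thresholding oracles
# ---------------------------------------------------------------------------


def histogram_by_loop(image: np.ndarray, n_levels: int = 256) -> np.ndarray:
    counts = np.zeros(n_levels, dtype=np.int64)
    for value in np.asarray(image).ravel():
        counts[int(value)] += 1
    return counts


def otsu_by_sweep(counts: np.ndarray) -> int:
    """Exhaustive between-class variance sweep, straight from the definition."""
    grays = np.arange(counts.size)
    total = counts.sum()
    best_t, best_val = 0, -1.0
    for t in range(counts.size - 1):
        n0 = counts[: t + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            val = 0.0
        else:
            mu0 = (counts[: t + 1] * grays[: t + 1]).sum() / n0
            mu1 = (counts[t + 1 :] * grays[t + 1 :]).sum() / n1
            val = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if val > best_val:
            best_val, best_t = val, t
    return best_t


def ksw_by_sweep(counts: np.ndarray) -> int:
    """Exhaustive Kapur entropy sweep over thresholds with two populated classes."""
    p = counts / counts.sum()

    def class_entropy(probs: np.ndarray) -> float:
        mass = probs.sum()
        h = 0.0
        for q in probs:
            if q > 0:
                q /= mass
                h -= q * np.log(q)
        return h

    best_t, best_val = None, -np.inf
    present = np.flatnonzero(counts)
    for t in range(int(present[0]), int(present[-1])):
        val = class_entropy(p[: t + 1]) + class_entropy(p[t + 1 :])
        if val > best_val:
            best_val, best_t = val, t
    return best_t


# ---------------------------------------------------------------------------
# maximin LP oracles
# ---------------------------------------------------------------------------


def maximin_by_vertex_enumeration(K: np.ndarray) -> float:
    """Exhaustive search over all vertices of the coverage polytope.

    Variables (a_1..a_k, rho); sum(a) = 1 always binds, so each vertex is
    defined by k further tight constraints chosen among the k covering
    rows (K a = rho) and the k sign constraints (a_i = 0).  Every
    combination is solved and feasibility-checked; the best feasible rho
    is the exact optimum.
    """
    k = K.shape[0]
    n_var = k + 1
    rows = []
    # covering rows: K a - rho = 0
    for j in range(k):
        rows.append(np.concatenate([K[j], [-1.0]]))
    # sign rows: a_i = 0
    for i in range(k):
        e = np.zeros(n_var)
        e[i] = 1.0
        rows.append(e)
    eq = np.concatenate([np.ones(k), [0.0]])
    best = -np.inf
    for combo in itertools.combinations(range(2 * k), k):
        A = np.vstack([eq] + [rows[j] for j in combo])
        if np.linalg.matrix_rank(A) < n_var:
            continue
        x, *_ = np.linalg.lstsq(A, np.concatenate([[1.0], np.zeros(k)]), rcond=None)
        a, rho = x[:k], x[k]
        if np.any(a < -1e-9):
            continue
        if np.any(K @ a < rho - 1e-9):
            continue
        best = max(best, rho)
    return float(best)


def maximin_by_linprog(K: np.ndarray) -> float:
    """Independent LP solve of the coverage program via scipy (HiGHS)."""
    k = K.shape[0]
    c = np.zeros(k + 1)
    c[-1] = -1.0
    res = linprog(
        c,
        A_ub=np.hstack([-K, np.ones((k, 1))]),
        b_ub=np.zeros(k),
        A_eq=np.hstack([np.ones((1, k)), np.zeros((1, 1))]),
        b_eq=[1.0],
        bounds=[(0, None)] * (k + 1),
        method="highs",
    )
    assert res.status == 0
    return float(-res.fun)


# ---------------------------------------------------------------------------
# phase congruency / FSIM reference (published algorithm, independent code)
# ---------------------------------------------------------------------------


def _centered_freq_grid(rows: int, cols: int):
    fy = np.fft.fftshift(np.fft.fftfreq(rows))
    fx = np.fft.fftshift(np.fft.fftfreq(cols))
    uy, ux = np.meshgrid(fy, fx, indexing="ij")
    radius = np.sqrt(ux**2 + uy**2)
    theta = np.arctan2(-uy, ux)
    return radius, theta


def pc_reference(
    image: np.ndarray,
    n_scales: int = 4,
    n_orient: int = 4,
    min_wavelength: float = 6.0,
    mult: float = 2.0,
    sigma_onf: float = 0.55,
    eps: float = 1e-4,
) -> np.ndarray:
    """Phase congruency E / (eps + sum A) from a log-Gabor quadrature bank.

    Centered-spectrum construction with explicit per-filter loops.
    """
    image = np.asarray(image, dtype=np.float64)
    rows, cols = image.shape
    radius, theta = _centered_freq_grid(rows, cols)
    centre = (rows // 2, cols // 2)
    radius[centre] = 1.0
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)
    spectrum = np.fft.fft2(image)
    energy = np.zeros_like(image)
    amplitude = np.zeros_like(image)
    for o in range(n_orient):
        angle = o * np.pi / n_orient
        diff = theta - angle
        d_theta = np.abs(np.arctan2(np.sin(diff), np.cos(diff)))
        spread = np.exp(-(d_theta**2) / (2.0 * (np.pi / n_orient / 1.5) ** 2))
        summed = np.zeros((rows, cols), dtype=np.complex128)
        for s in range(n_scales):
            wavelength = min_wavelength * mult**s
            log_gabor = np.exp(
                -((np.log(radius * wavelength)) ** 2)
                / (2.0 * np.log(sigma_onf) ** 2)
            )
            log_gabor = log_gabor * lowpass
            log_gabor[centre] = 0.0
            filt = np.fft.ifftshift(log_gabor * spread)
            response = np.fft.ifft2(spectrum * filt)
            summed += response
            amplitude += np.abs(response)
        energy += np.abs(summed)
    return energy / (eps + amplitude)


def scharr_gradient(image: np.ndarray) -> np.ndarray:
    """Scharr 3x3 gradient magnitude (the operator of the FSIM literature)."""
    image = np.asarray(image, dtype=np.float64)
    dx = np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0
    gx = convolve2d(image, dx, mode="same", boundary="symm")
    gy = convolve2d(image, dx.T, mode="same", boundary="symm")
    return np.sqrt(gx**2 + gy**2)


def fsim_reference(
    image_a: np.ndarray,
    image_b: np.ndarray,
    t1: float = 0.85,
    t2: float = 160.0,
) -> float:
    """FSIM per the published definition with the Scharr gradient."""
    pc1 = pc_reference(image_a)
    pc2 = pc_reference(image_b)
    g1 = scharr_gradient(image_a)
    g2 = scharr_gradient(image_b)
    s_pc = (2 * pc1 * pc2 + t1) / (pc1**2 + pc2**2 + t1)
    s_g = (2 * g1 * g2 + t2) / (g1**2 + g2**2 + t2)
    pc_m = np.maximum(pc1, pc2)
    return float((s_pc * s_g * pc_m).sum() / pc_m.sum())
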