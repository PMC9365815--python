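"""Segmentation quality measures for bi-level thresholding.

Four complementary measures, all pure functions:

* misclassification error (ME): fraction of pixels assigned to the wrong
  class relative to a ground-truth mask; 0 best, 1 worst.
* region nonuniformity (NU): gray-value variance inside the segmented
  foreground relative to the whole-image variance, weighted by the
  foreground fraction; approaches 0 for a well-segmented image.
* feature similarity (FSIM): similarity of two gray images combining
  phase-congruency and gradient-magnitude similarity maps, weighted by the
  pointwise maximum phase congruency; 1 best.
* mean intersection-over-union (mIoU): average of per-class
  TP / (TP + FP + FN) over the two classes, in percent; 100 best.

Phase congruency is computed from a multi-scale, multi-orientation
log-Gabor quadrature filter bank as PC = |sum of complex responses| /
(eps + sum of response amplitudes), with the conventional bank parameters
of the FSIM literature (4 scales, 4 orientations, minimum wavelength 6,
scale multiplier 2, sigma_onf 0.55).  Gradients use the 3x3 Sobel operator
scaled to a centred-difference response (divided by 4) with reflective
boundary handling, so that the conventional FSIM constant T2 = 160 applies
to 8-bit images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MetricsReport",
    "misclassification_error",
    "region_nonuniformity",
    "gradient_magnitude",
    "phase_congruency",
    "fsim",
    "mean_iou",
    "evaluate_mask",
]

# FSIM stabilisation constants for 8-bit gray images
T1_DEFAULT = 0.85
T2_DEFAULT = 160.0
PC_EPS = 1e-4

# log-Gabor bank (conventional FSIM parameters)
PC_N_SCALES = 4
PC_N_ORIENT = 4
PC_MIN_WAVELENGTH = 6.0
PC_MULT = 2.0
PC_SIGMA_ONF = 0.55
_PC_MIN_SIZE = 16


@dataclass(frozen=True)
class MetricsReport:
    """The four quality measures of one (image, mask, ground truth) triple."""

    me: float
    nu: float
    fsim: float
    miou: float


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError(f"{name} must be binary (values 0/1)")
    return mask.astype(bool)


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def misclassification_error(gt_mask: np.ndarray, test_mask: np.ndarray) -> float:
    """Fraction of pixels whose class disagrees with the ground truth.

    ME = 1 - (|B_gt ∩ B_test| + |F_gt ∩ F_test|) / total pixels.
    """
    gt = _as_binary(gt_mask, "gt_mask")
    test = _as_binary(test_mask, "test_mask")
    _check_same_shape(gt, test)
    agree = int(np.count_nonzero(gt == test))
    return 1.0 - agree / gt.size


def region_nonuniformity(image: np.ndarray, mask: np.ndarray) -> float:
    """Foreground-variance ratio weighted by foreground fraction.

    NU = (|F| / N) * (var of gray values inside F / var of all gray
    values); an empty foreground scores 0, a constant image is undefined.
    """
    image = np.asarray(image, dtype=np.float64)
    fg = _as_binary(mask, "mask")
    _check_same_shape(image, fg)
    total_var = float(image.var())
    if total_var == 0.0:
        raise ValueError("NU is undefined for a constant image")
    n_fg = int(np.count_nonzero(fg))
    if n_fg == 0:
        return 0.0
    fg_var = float(image[fg].var())
    return (n_fg / image.size) * (fg_var / total_var)


def gradient_magnitude(image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude G = sqrt(Gx^2 + Gy^2), reflective borders.

    The 3x3 Sobel responses are divided by 4 so a unit intensity step
    produces a unit gradient, the scale the FSIM constant T2 assumes.
    """
    image = np.asarray(image, dtype=np.float64)
    gx = ndimage.sobel(image, axis=1, mode="reflect") / 4.0
    gy = ndimage.sobel(image, axis=0, mode="reflect") / 4.0
    return np.hypot(gx, gy)


def _log_gabor_bank(shape: tuple[int, int]) -> list[list[np.ndarray]]:
    """Frequency-domain log-Gabor filters, [orientation][scale].

    Radial part: log-Gaussian around centre frequency 1/wavelength with a
    high-frequency roll-off; angular part: Gaussian in angle around the
    orientation axis, one-sided so the spatial response is a quadrature
    (complex analytic) pair.
    """
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0  # avoid log(0) at DC; the DC gain is zeroed anyway
    theta = np.arctan2(-fy, fx)

    # Butterworth low-pass keeps the bank away from the Nyquist corners
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)

    log_sigma = np.log(PC_SIGMA_ONF)
    radials = []
    for s in range(PC_N_SCALES):
        f0 = 1.0 / (PC_MIN_WAVELENGTH * PC_MULT**s)
        g = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * log_sigma**2)) * lowpass
        g[0, 0] = 0.0
        radials.append(g)

    theta_sigma = np.pi / PC_N_ORIENT / 1.5
    bank: list[list[np.ndarray]] = []
    for o in range(PC_N_ORIENT):
        angle = o * np.pi / PC_N_ORIENT
        d_theta = np.arctan2(
            np.sin(theta - angle), np.cos(theta - angle)
        )  # wrapped to (-pi, pi], one-sided
        spread = np.exp(-(d_theta**2) / (2.0 * theta_sigma**2))
        bank.append([g * spread for g in radials])
    return bank


def phase_congruency(image: np.ndarray) -> np.ndarray:
    """Phase congruency map PC = E / (eps + sum_n A_n), in [0, 1].

    E is the magnitude of the summed complex filter responses (the local
    energy) and A_n the per-filter amplitudes; phase-consistent structure
    (edges, lines) scores near 1 regardless of contrast, featureless
    regions near 0.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if min(image.shape) < _PC_MIN_SIZE:
        raise ValueError(
            f"image too small for the filter bank (min side {_PC_MIN_SIZE})"
        )
    spectrum = np.fft.fft2(image)
    energy = np.zeros(image.shape)
    amplitude = np.zeros(image.shape)
    for orientation in _log_gabor_bank(image.shape):
        resp_sum = np.zeros(image.shape, dtype=np.complex128)
        for filt in orientation:
            resp = np.fft.ifft2(spectrum * filt)
            resp_sum += resp
            amplitude += np.abs(resp)
        energy += np.abs(resp_sum)
    return energy / (PC_EPS + amplitude)


def fsim(
    image_a: np.ndarray,
    image_b: np.ndarray,
    t1: float = T1_DEFAULT,
    t2: float = T2_DEFAULT,
) -> float:
    """Feature similarity of two gray images, in [0, 1].

    Pointwise similarity S_PC of the phase-congruency maps and S_G of the
    gradient magnitudes are combined as S_PC * S_G and averaged with the
    pointwise maximum phase congruency as weight.
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    _check_same_shape(a, b)
    pc1, pc2 = phase_congruency(a), phase_congruency(b)
    g1, g2 = gradient_magnitude(a), gradient_magnitude(b)
    s_pc = (2.0 * pc1 * pc2 + t1) / (pc1**2 + pc2**2 + t1)
    s_g = (2.0 * g1 * g2 + t2) / (g1**2 + g2**2 + t2)
    s_l = s_pc * s_g
    pc_m = np.maximum(pc1, pc2)
    denom = float(pc_m.sum())
    if denom <= 0.0:
        # both maps devoid of features (e.g. constant images): unweighted mean
        return float(s_l.mean())
    return float((s_l * pc_m).sum() / denom)


def mean_iou(gt_mask: np.ndarray, test_mask: np.ndarray) -> float:
    """Mean intersection-over-union of the two classes, in percent.

    Per class: TP / (TP + FP + FN); a class absent from both masks scores
    1.  Identical masks give 100, disjoint covering masks give 0.
    """
    gt = _as_binary(gt_mask, "gt_mask")
    test = _as_binary(test_mask, "test_mask")
    _check_same_shape(gt, test)
    ious = []
    for cls in (False, True):
        g = gt == cls
        t = test == cls
        union = int(np.count_nonzero(g | t))
        if union == 0:
            ious.append(1.0)
        else:
            ious.append(int(np.count_nonzero(g & t)) / union)
    return 100.0 * float(np.mean(ious))


def evaluate_mask(
    image: np.ndarray,
    mask: np.ndarray,
    gt_mask: np.ndarray | None = None,
    gray_levels: int = 256,
) -> MetricsReport:
    """All four measures for one segmentation of one image.

    FSIM compares the original image with the mask rendered back to gray
    ({0, L-1}); ME and mIoU require a ground truth and are reported as NaN
    without one.
    """
    mask_gray = np.asarray(mask, dtype=np.float64) * (gray_levels - 1)
    report_fsim = fsim(image, mask_gray)
    nu = region_nonuniformity(image, mask)
    if gt_mask is None:
        return MetricsReport(me=float("nan"), nu=nu, fsim=report_fsim, miou=float("nan"))
    return MetricsReport(
        me=misclassification_error(gt_mask, mask),
        nu=nu,
        fsim=report_fsim,
        miou=mean_iou(gt_mask, mask),
    )
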