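"""Synthetic two-level test images with exact ground truth.

Piecewise-constant patterns (bright circles or squares on a darker
background) corrupted by additive Gaussian noise.  Because the noiseless
template contains exactly two gray values, the ideal segmentation is known
by construction, which makes these images the canonical benchmark for
bi-level thresholding algorithms: the histogram of the noisy image is a
two-Gaussian mixture whose modes overlap as the noise grows, while the
ground-truth mask stays fixed.

Conventions: 8-bit gray (levels 0..255), 0-based row-major pixel
coordinates, pixel-center rasterization (a pixel belongs to a shape iff its
integer center satisfies the shape inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

L = 256  # number of gray levels of the canonical 8-bit representation

__all__ = [
    "L",
    "Circle",
    "Square",
    "SyntheticSpec",
    "GroundTruthPair",
    "default_circles_spec",
    "default_squares_spec",
    "make_circles",
    "make_squares",
    "add_gaussian_noise",
]


@dataclass(frozen=True)
class Circle:
    """Disc: pixels (r, c) with (r - center_row)**2 + (c - center_col)**2 <= radius**2."""

    center_row: int
    center_col: int
    radius: int


@dataclass(frozen=True)
class Square:
    """Axis-aligned square of ``side`` pixels whose top-left pixel is (top, left)."""

    top: int
    left: int
    side: int


Shape = Union[Circle, Square]


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic ground-truth image.

    The emitted image is a pure function of this object: the noiseless
    template is ``background_gray`` everywhere except inside the shapes,
    where it is ``foreground_gray``; i.i.d. zero-mean Gaussian noise of
    standard deviation ``noise_sigma`` (gray-level units) is then added,
    rounded half-away-from-zero and clipped to [0, L-1].
    """

    height: int = 256
    width: int = 256
    background_gray: int = 50
    foreground_gray: int = 150
    shapes: tuple[Shape, ...] = field(default_factory=tuple)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be positive")
        for g in (self.background_gray, self.foreground_gray):
            if not (0 <= g <= L - 1):
                raise ValueError(f"gray level {g} outside [0, {L - 1}]")
        if self.background_gray == self.foreground_gray:
            raise ValueError("foreground_gray must differ from background_gray")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for shape in self.shapes:
            self._check_bounds(shape)

    def _check_bounds(self, shape: Shape) -> None:
        if isinstance(shape, Circle):
            if shape.radius < 1:
                raise ValueError("circle radius must be >= 1")
            if (
                shape.center_row - shape.radius < 0
                or shape.center_row + shape.radius > self.height - 1
                or shape.center_col - shape.radius < 0
                or shape.center_col + shape.radius > self.width - 1
            ):
                raise ValueError(f"circle {shape} extends outside the image")
        elif isinstance(shape, Square):
            if shape.side < 1:
                raise ValueError("square side must be >= 1")
            if (
                shape.top < 0
                or shape.left < 0
                or shape.top + shape.side > self.height
                or shape.left + shape.side > self.width
            ):
                raise ValueError(f"square {shape} extends outside the image")
        else:  # pragma: no cover - defensive
            raise TypeError(f"unknown shape type {type(shape)!r}")


@dataclass(frozen=True)
class GroundTruthPair:
    """A noisy gray image together with its exact binary foreground mask."""

    image: np.ndarray  # uint8, shape (H, W)
    mask: np.ndarray  # uint8 in {0, 1}, same shape; 1 = foreground


def default_circles_spec(noise_sigma: float = 30.0, seed: int = 0) -> SyntheticSpec:
    """Bright circles (gray 150) on a darker background (gray 50), 256x256.

    Three disjoint discs of mixed radii; the default noise level makes the
    two histogram modes overlap into a genuinely bimodal, full-support
    histogram.
    """
    return SyntheticSpec(
        height=256,
        width=256,
        background_gray=50,
        foreground_gray=150,
        shapes=(
            Circle(70, 80, 40),
            Circle(170, 180, 50),
            Circle(190, 60, 28),
        ),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def default_squares_spec(noise_sigma: float = 50.0, seed: int = 0) -> SyntheticSpec:
    """Bright squares (gray 225) on a darker background (gray 75), 256x256."""
    return SyntheticSpec(
        height=256,
        width=256,
        background_gray=75,
        foreground_gray=225,
        shapes=(
            Square(30, 30, 70),
            Square(140, 130, 90),
            Square(40, 170, 50),
        ),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _rasterize(spec: SyntheticSpec) -> np.ndarray:
    """Exact binary mask of the union of shape interiors (uint8 {0,1})."""
    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width]
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for shape in spec.shapes:
        if isinstance(shape, Circle):
            mask |= (rows - shape.center_row) ** 2 + (
                cols - shape.center_col
            ) ** 2 <= shape.radius**2
        else:
            mask |= (
                (rows >= shape.top)
                & (rows < shape.top + shape.side)
                & (cols >= shape.left)
                & (cols < shape.left + shape.side)
            )
    return mask.astype(np.uint8)


def _render(spec: SyntheticSpec) -> GroundTruthPair:
    mask = _rasterize(spec)
    template = np.where(mask == 1, spec.foreground_gray, spec.background_gray).astype(
        np.uint8
    )
    image = add_gaussian_noise(template, spec.noise_sigma, spec.seed)
    return GroundTruthPair(image=image, mask=mask)


def make_circles(spec: SyntheticSpec) -> GroundTruthPair:
    """Render a circles spec: noisy image plus its exact ground-truth mask."""
    for shape in spec.shapes:
        if not isinstance(shape, Circle):
            raise ValueError("make_circles requires all shapes to be circles")
    return _render(spec)


def make_squares(spec: SyntheticSpec) -> GroundTruthPair:
    """Render a squares spec: noisy image plus its exact ground-truth mask."""
    for shape in spec.shapes:
        if not isinstance(shape, Square):
            raise ValueError("make_squares requires all shapes to be squares")
    return _render(spec)


def add_gaussian_noise(image: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add i.i.d. N(0, sigma^2) noise per pixel, round half-away-from-zero, clip.

    Deterministic given ``seed``; ``sigma`` is in gray-level units.  With
    ``sigma == 0`` the input is returned unchanged (as a copy).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if sigma == 0:
        return image.astype(np.uint8, copy=True)
    rng = np.random.default_rng(seed)
    noisy = image.astype(np.float64) + rng.normal(0.0, sigma, size=image.shape)
    rounded = np.copysign(np.floor(np.abs(noisy) + 0.5), noisy)
    return np.clip(rounded, 0, L - 1).astype(np.uint8)
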