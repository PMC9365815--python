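# Methods

## Model

A gray image `F` with levels `G = {0, ..., L-1}` (L = 256 throughout) is
reduced to its level sets: `omega_l` is the set of pixels with value `l`
and `C_l = |omega_l|`, with `N = sum C_l` pixels in total.  Bi-level
thresholding picks a single cut `t` and maps every pixel with value
`<= t` to background (0) and `> t` to foreground (1).  The underlying
assumption is the usual one for histogram-based segmentation: foreground
and background have different gray-level distributions, so a good cut
separates the two modes of the (noisy) histogram.

### Weighted Parzen window

Classical Parzen estimation places one kernel of width `h_n = c / sqrt(n)`
on each of `n` samples and averages.  On the gray axis all `C_l` samples
of a level coincide at `g = l`, so the class-conditional estimate
collapses to a single normalized Gaussian `phi(g; l, sigma_l)` with

    sigma_l = max(c / sqrt(C_l), sigma_min).

Instead of weighting these kernels by the histogram (`C_l / N`), the
weighted Parzen window chooses the mixture weights `a` by the maximin
linear program

    max rho   s.t.  sum a_i = 1,   K a >= rho 1,   a >= 0,

where `K[j, i] = phi(g_j; g_i, sigma_i)` over the distinct populated
levels.  The fitted `p_hat(g) = sum a_i phi(g; g_i, sigma_i)` is not a
density estimate of the data but a *support description*: every observed
level is covered at height at least `rho*`, and `rho*` is the largest
coverage guarantee attainable.  The implied bounds `0 <= a_i <= 1` and
`0 <= rho <= (sqrt(2 pi) sigma_min_active)^(-d)` hold at any feasible
point and are checked by `validate_solution`.

Posing the program over distinct levels rather than pixels is exact:
pixels sharing a gray value contribute identical covering constraints and
interchangeable weights, so merging them changes nothing while capping
the problem at 256 variables.  Pixel multiplicities still matter — they
enter through the kernel widths.

### Solving the program

`rho* > 0` always (the diagonal of `K` is positive), so substituting
`u = a / rho` turns the program into the linear program of a matrix game:
`min 1'u : K u >= 1, u >= 0`, with `rho* = 1 / sum(u)`.  The solver runs
a dense primal simplex on the dual `max 1'v : K'v <= 1, v >= 0`, whose
slack basis is feasible with a strictly positive right-hand side — no
artificial phase and far less degeneracy than the direct form, whose
right-hand side is almost entirely zero (in experiments during
development the direct two-phase tableau stalled for tens of thousands
of degenerate pivots on real histograms; the game form solves the same
instances in a few hundred).  Pivoting: Dantzig's largest-coefficient
entering rule, switching permanently to Bland's smallest-index rule
after 100 consecutive degenerate pivots, which makes cycling impossible;
minimum-ratio leaving with ties broken toward the smallest basic index.
Pivot tolerance 1e-9; the iteration cap is reported as an explicit
non-optimal status, never as a silent answer.  The weights are recovered
from the dual multipliers (`a = y / sum y`, `rho* = 1 / sum y`) and
re-certified against the original constraints.  Everything is
deterministic for a fixed instance.

### From the LP solution to a threshold

The level set `p_hat = rho*` is the boundary between covered and
uncovered gray values.  Two regimes:

1. **Separated classes.**  If the histogram has a hole between the class
   modes, the integer gray values in the hole satisfy `p_hat < rho*`
   (nothing obliges the mixture to cover unobserved levels).  The
   threshold is the floor of the midpoint of the sub-`rho*` run with the
   smallest mean `p_hat`, restricted to runs whose two sides each hold at
   least 1% of the pixels.  The mass guard exists because a handful of
   stray tail pixels can open spurious sub-`rho*` gaps near the extremes
   of the range; a class boundary must have a class on each side.  On a
   noiseless two-level image this rule reduces to "cut in the middle of
   the empty band", which reproduces the ground truth exactly for any
   such image.

2. **Overlapping classes.**  When every level between the modes is
   populated, all of them are covering constraints, and at the optimum
   the covering constraints equalize: the vertex solves `K a = rho* 1`,
   so `p_hat` equals `rho*` at *every* populated level and carries no
   interior minimum.  This is a structural property of the maximin
   program, not a numerical artifact; the boundary information must then
   come from the data density itself.  The fallback is the valley rule:
   smooth the count histogram with a Gaussian at Silverman's bandwidth
   `h = 0.9 min(sd, IQR/1.34) N^(-1/5)` (computed over the pixel
   population, floored at one gray level) and place `t` at the argmin
   between the two most prominent interior modes.  The saturation bins 0
   and L-1 are replaced by their inner neighbours before mode finding —
   clipped noise piles mass there and would otherwise fake a mode at the
   range boundary.  If the smoothed histogram is unimodal there is no
   valley and the between-class-variance (Otsu) optimum is used as the
   last resort.

The original formulation leaves this step open — comparing class
densities to `rho` is not operational once one observes that every
populated level satisfies `p_hat >= rho*` by construction — so the rule
above is this package's own operationalization; it is the design point
most likely to differ from other implementations of the idea.

All argmax/argmin sweeps in the package break ties toward the smallest
gray level, so every method is deterministic.  Images with fewer than two
distinct levels raise `DegenerateImageError` — no threshold exists.

## Baselines

* **Otsu**: exhaustive sweep of the between-class variance
  `w0 w1 (mu0 - mu1)^2` over all cuts, from the normalized histogram.
* **Kapur / KSW**: exhaustive sweep of the summed class entropies with
  the `0 log 0 = 0` convention.  Candidate cuts are restricted to those
  leaving both classes populated; without that restriction the criterion
  can prefer an empty-class split on spiky histograms (an all-mass class
  has zero entropy, the same score as the degenerate split, while a
  one-sided split scores the full distribution entropy).

Both are re-implemented from their standard formulations and verified
against independent brute-force sweeps in the tests.

## Quality metrics

* `ME = 1 - (|B_gt ∩ B_t| + |F_gt ∩ F_t|) / N`, in [0, 1].
* `NU = (|F_t| / N) * (var_F / var_image)`; an empty foreground scores 0,
  a constant image is undefined (error).  Foreground is the thresholded
  foreground; variances are of the original gray values.
* `FSIM`: pointwise products of the phase-congruency similarity
  `S_PC = (2 PC1 PC2 + T1) / (PC1^2 + PC2^2 + T1)` and the gradient
  similarity `S_G = (2 G1 G2 + T2) / (G1^2 + G2^2 + T2)`, averaged with
  weight `max(PC1, PC2)`; constants `T1 = 0.85`, `T2 = 160` (8-bit
  scale).  Phase congruency `PC = E / (eps + sum A_n)` comes from a
  log-Gabor quadrature bank with the conventional parameters of the FSIM
  literature: 4 scales, 4 orientations, minimum wavelength 6, scale
  multiplier 2, `sigma_onf = 0.55`, `eps = 1e-4`, one-sided Gaussian
  angular spread (`sigma_theta = pi/4/1.5`), Butterworth low-pass
  (cutoff 0.45, order 15) and zero DC gain.  Gradients are 3x3 Sobel
  responses divided by 4 (unit step -> unit gradient, the scale `T2`
  assumes) with reflective borders.  When comparing an image against a
  segmentation, the mask is rendered to gray as {0, 255}.  Images
  smaller than 16 px per side are rejected (filter support).
* `mIoU`: mean over the two classes of `TP / (TP + FP + FN)`, in
  percent; a class absent from both masks counts as full overlap.

The exact filter bank and gradient operator behind published FSIM
numbers vary between implementations; the tests therefore check
agreement with an independently coded implementation of the published
algorithm to 0.05 mean absolute difference rather than bit-exactness.

## Synthetic benchmark generator

The generator emulates the standard two-level thresholding benchmarks:
piecewise-constant shapes — circles of gray 150 on background 50, or
squares of 225 on 75 — on a 256x256 canvas, corrupted by i.i.d. additive
Gaussian noise, rounded half-away-from-zero and clipped to [0, 255].
The mask is rasterized at pixel centres and is exact and independent of
the noise; the emitted pair is a pure function of the spec (including
the seed).  Default noise levels: sigma 30 for circles and 50 for
squares — chosen once so that the two histogram modes overlap into a
genuinely bimodal, full-support histogram, the regime that exercises
the valley fallback rather than the trivial gap rule.  Shape placement
is arbitrary (three disjoint shapes of mixed sizes, about 23% foreground).

What passing on these images does and does not show: the generator
produces stationary Gaussian pixel noise on a two-level template, so
success here demonstrates correct mechanics and robustness to histogram
overlap, but not performance under textured foregrounds, illumination
gradients, spatially correlated noise, or multi-modal scenes — none of
which a histogram-only method can see.

## Problem sizes and tolerances in the tests

The acceptance-style checks use 200 random LP instances with at most six
samples against exhaustive vertex enumeration (1e-3) and an independent
LP solver (1e-8); 100 random histograms for the baseline sweeps (exact
equality); 25 noise realisations of the circles benchmark for the
robustness band; and trapezoidal quadrature at step 0.005 over
[-20, 276] for density normalization (1e-6).  These sizes keep the whole
suite under a minute while leaving each property statistically
meaningful.

## Known limitations

* Histogram-only: spatial structure is invisible to the method; two
  images with equal histograms threshold identically.
* Bi-level only; no multi-level extension.
* The valley fallback assumes each class holds a non-negligible share of
  the pixels (1% for the gap guard, and modes prominent enough to
  survive Silverman smoothing); very small foregrounds on heavy-tailed
  noise may be missed.
* The saturation-bin exclusion means a genuine mode exactly at gray 0 or
  255 cannot anchor the valley interval.
* FSIM values depend on the filter-bank conventions documented above and
  are comparable within this package, not bit-for-bit with other codes.
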