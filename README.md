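# wpwlpt — bi-level image thresholding with a weighted Parzen window fitted by linear programming

`wpwlpt` segments a single-channel gray image into foreground and
background with one threshold `t` (Eq. below), selecting `t` from a
*weighted Parzen window*: a kernel mixture over the observed gray levels
whose weights are chosen by a maximin linear program rather than by the
histogram.  The package targets workflows that evaluate thresholding
algorithms quantitatively — nondestructive-testing imagery, microscopy,
and synthetic benchmarks — and ships the Otsu and Kapur (KSW) baselines,
four segmentation quality metrics (ME, NU, FSIM, mIoU), and a synthetic
ground-truth image generator so everything is testable without external
data.

## The method

A threshold `t` induces the binary map

```
f_t(x, y) = 0  if f(x, y) <= t      (background)
            1  if f(x, y) >  t      (foreground)
```

For each populated gray level `l` with pixel count `C_l`, place a
normalized Gaussian kernel `phi(g; l, sigma_l)` with the Parzen-window
width `sigma_l = max(c / sqrt(C_l), sigma_min)` (`c = 1`,
`sigma_min = 0.5` by default).  The mixture weights `a` and the coverage
level `rho` solve the linear program

```
max  rho
s.t. sum_i a_i                      = 1
     sum_i a_i phi(g_j; g_i, s_i) >= rho    for every populated level g_j
     a_i                           >= 0
```

so the fitted density `p_hat(g) = sum_i a_i phi(g; g_i, sigma_i)` covers
every observed gray level at height at least `rho*`, with `rho*` — the
guaranteed minimum coverage — as large as possible.  The level set
`p_hat = rho*` delineates the boundary of the gray-value distribution:
the threshold is placed in the sub-`rho*` gap between the two classes
when the histogram has one, and at the valley of the Parzen-smoothed
histogram when the class modes overlap (see `docs/methods.md` for the
exact rule).  The program is solved by a dense primal simplex written in
this package; an equivalent matrix-game form keeps it nondegenerate and
a vertex-enumeration oracle plus an independent LP solver certify it in
the tests.

Quality measures: misclassification error `ME` (0 best), region
nonuniformity `NU` (0 best), feature similarity `FSIM` (1 best, from
phase congruency and gradient magnitude), and mean
intersection-over-union `mIoU` in percent (100 best).

## Worked example

```python
from wpwlpt import (default_circles_spec, make_circles,
                    wpwlpt_threshold, evaluate_mask)

pair = make_circles(default_circles_spec(noise_sigma=30.0, seed=1))
result = wpwlpt_threshold(pair.image)
report = evaluate_mask(pair.image, result.mask, pair.mask)
print(f"threshold t* = {result.threshold}, coverage rho* = {result.rho:.6f}")
print(f"ME = {report.me:.4f}  NU = {report.nu:.4f}  "
      f"FSIM = {report.fsim:.4f}  mIoU = {report.miou:.1f}%")
```

prints

```
threshold t* = 114, coverage rho* = 0.003962
ME = 0.0398  NU = 0.0536  FSIM = 0.3282  mIoU = 89.4%
```

The generated image is the classic bright-circles-on-dark benchmark
(gray 150 shapes on gray 50, 256x256) under Gaussian noise of standard
deviation 30, which makes the two histogram modes overlap; the exact
ground-truth mask comes for free.  The selected threshold 114 sits in
the inter-class valley, misclassifies 4.0% of the pixels and overlaps
the ground truth at 89.4% mean IoU; Otsu on the same image picks t = 95
(ME 0.0564, mIoU 86.4%).

The same pipeline is available from the shell:

```
wpwlpt synth --pattern circles --sigma 30 --seed 1 --out bench/
wpwlpt threshold bench/circles.png --method wpwlpt --out-mask mask.png
wpwlpt evaluate --image bench/circles.png --mask mask.png --gt bench/circles_gt.png
wpwlpt benchmark bench/circles.png:bench/circles_gt.png --methods otsu,ksw,wpwlpt
```

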