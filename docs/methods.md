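# Methods

## The relaxation model

A droplet carrying magnetic nanoparticles, suspended in an alginate
solution, deforms into a prolate ellipsoid under a weak uniform magnetic
field and relaxes back toward a sphere when the field is removed. Each
geometric magnitude y(t) — aspect ratio (dimensionless), major diameter
(μm), or area (μm²) — is modeled by the stretched-exponential
(Kohlrausch–Williams–Watts) law in its rising form

    y(t) = a + b · (1 − exp(−(t/λ_c)^β)),

with `a` the value at t = 0, `a + b` the long-time plateau, λ_c > 0 the
characteristic time in seconds and β > 0 the stretching exponent
(β = 1: single relaxation time; β < 1: broadened relaxation-time
distribution). Elongation curves rise (b > 0), recovery curves fall
(b < 0). The decaying parameterization `a' + b'·exp(−(t/λ_c)^β)` is the
affine twin (a' = a + b, b' = −b) and is available behind a flag; the
rising form is canonical here because the tabulated reference
parameters quote `a` as the initial value with positive elongation and
negative recovery amplitudes, which only the rising form satisfies.
For a relaxing spherical droplet, λ_c = η_eff·R₀/σ links the time scale
to the effective internal viscosity, initial radius, and interfacial
tension; the data do not allow η_eff and σ to be estimated separately,
so the package only exposes the λ_c–diameter regression, not the two
physical factors.

## Pipeline stages and the choices inside them

**Enhancement.** Median filter with a (2r+1)² window, default r = 1,
edge-replicated borders (no halo, dimensions preserved). Global
histogram equalization v → round(255·cdf(v)) — monotone, so intensity
order is preserved and it is idempotent up to one gray level. When both
are applied the median filter runs first (equalizing amplified noise is
counterproductive).

**Segmentation.** A two-component Gaussian mixture is fitted to the
256-bin intensity histogram by EM on the binned data (each level
weighted by its count). Initialization splits the histogram at its
median level; three additional seeded, jittered restarts are run and
the highest-likelihood solution kept. Component standard deviations are
floored at 0.5 gray level (flagged) so two-level noise-free histograms
cannot collapse the likelihood. The threshold is the root of
w₁·φ(t; μ₁, σ₁) = w₂·φ(t; μ₂, σ₂) inside (μ₁, μ₂) — a quadratic when
σ₁ ≠ σ₂ — falling back to the weighted midpoint w₂μ₁ + w₁μ₂ (logged) if
no root lies in the interval. Masks are refined by closing with a disk
(default radius 1, sealing 1-px boundary gaps), hole filling, and
removal of components below 25 px or touching the border (partially
observed droplets are excluded, mirroring the selection of
non-interacting droplets). Components use 8-connectivity. The threshold
is estimated per frame; a fixed-threshold mode exists for
reproducibility studies.

*Equalization and thresholding.* The pipeline default fits the mixture
on the median-filtered, **unequalized** intensities. Equalization is a
monotone remap that adds no information to a histogram threshold, and
by design it flattens the histogram — both classes are pushed toward
uniform, the Gaussian-intersection threshold becomes unstable, and in
scene sweeps the per-droplet Jaccard overlap degrades badly whenever
droplets cover a minor fraction of the field. On unequalized frames the
chain achieves Jaccard ≥ 0.99 down to droplet fractions of 0.5%.
Equalization remains available (`--no-equalize` inverted, config flag)
for data where contrast, not class shape, is the limiting factor.

**Features.** Each component's coordinate covariance C (population
second central moments, no discretization correction) defines the
moment-equivalent ellipse: axis lengths 4·√eig(C) px, orientation along
the principal eigenvector (angle from the column axis, (−π/2, π/2]);
area is the pixel count times (μm/px)². On rasterized ellipses with
semi-axes ≥ 10 px this recovers axes within 2% and is rotation
invariant; the discretization bias (+1/12 px² per axis variance) is
< 0.3% for the smallest droplets analyzed. Tracking is
nearest-centroid with a gate of 0.5 × the droplet's current major
diameter per frame step; ties are resolved by minimum area change
(logged); tracks missing from > 20% of frames are dropped.

**KWW fitting.** Sum-of-squared-residuals minimization over
(a, b, λ_c, β) with DE/rand/1/bin: population 40 (10 per parameter),
F = 0.8, CR = 0.9, at most 300 generations, stagnation tolerance 1e-8,
Latin-hypercube initialization, fully seeded, followed by a Nelder–Mead
polish from the DE optimum (xatol 1e-12, fatol 1e-16). Bounds default
to: a within the observed range ± 3 data spans, b sign-free within ± 3
spans, λ_c ∈ [0.1 s, 10·t_max], β ∈ [0.1, 15] (observed exponents reach
12, so the cap must exceed that). On noiseless curves sampled at 0.5 s
over 0–40 s this recovers all four parameters to better than 0.1%
(machine precision after polish); flat curves (zero span) are rejected
as unidentifiable, and at least 5 points are required.

**Statistics.** The design is the balanced full factorial 5 droplets ×
3 magnitudes × 2 processes, one fitted curve per cell (n = 30). The
ANOVA is additive (no interactions; residual df = 22); for balanced
data each factor sum of squares is the between-levels sum
Σ n_l (ȳ_l − ȳ)², and F is the ratio to the residual mean square. The
MANOVA uses the same additive decomposition on the SSCP matrices with
the Pillai trace V = tr(H(H+E)⁻¹) and the standard approximate-F
transformation; with a single response it reduces exactly to the
univariate F, and H = 0 short-circuits to V = 0. Sums of squares are
computed sequentially in the order magnitude, droplet, process — for
this balanced design all orders coincide; the order is fixed only for
determinism. Tukey HSD uses the additive-model residual mean square and
df with the studentized-range distribution; intervals are
diff ± q(0.95; 5, 22)·√(MS_e/6), which reproduces the published
constant half-width ≈ 4.846. Boxplot fences are Q1 − 1.5·IQR and
Q3 + 1.5·IQR with quartiles by linear interpolation at positions
1 + (n−1)p (the common default in mainstream statistical software);
under this convention the flagged stretching exponents are exactly
{4.10, 4.95, 12.0}. Bootstrap intervals are percentile intervals over
1000 seeded with-replacement resamples of the original size (no
parametric assumption, no BCa). The β interval pools all 30 values,
removes the fence outliers, and bootstraps the mean. The λ_c–diameter
regression first fits a line with intercept, tests the intercept at
α = 0.05, and refits through the origin (slope Σxy/Σx²) when it is not
significant; the default point set pairs each droplet's initial major
diameter (elongation-fit `a`, major magnitude) with its recovery λ_c
for the major magnitude, and is config-exposed because the published
pairing is not stated. All significance levels are fixed at 0.05.

Two internal inconsistencies of the published tables are handled as
follows: the published Process F (0.0340) disagrees with its own mean
squares and p-value (MS ratio 0.2225, p = 0.6417), so the MS ratio is
reported; and the published approximate-F column of the MANOVA table is
tenfold larger than its own Pillai/p columns imply, so the Pillai and
p values are the quantities this package reproduces. Recomputing the
Pillai trace for Magnitude from the published 4-significant-figure
parameter table gives 0.9678 (confirmed independently with R's
`manova()`), not the published 0.95638 — multivariate statistics are
more sensitive than the ANOVA to input rounding, and the published
value evidently derives from unrounded fit parameters.

## The synthetic-scene generator

Scenes emulate the measurable content of the experiment: five
non-interacting elliptical droplets of distinct sizes, darker (default
60 gray levels) than the background (190), with per-class Gaussian
noise (sd 8 each; mode separation 130 ≫ 3 sd guarantees bimodality),
salt-and-pepper impulses at a 0.2% pixel fraction, and geometry driven
by the tabulated per-droplet KWW parameters for AR and major diameter
(minor and area follow from the ellipse identities). Default frame
times follow the published sampling: 0, 2, 6, 10, 15, 18, 23, 26 s for
elongation and 0, 6, 15, 26, 54, 74, 92, 111, 125 s for recovery.
Pixels belong to a droplet iff their centers satisfy the rotated
ellipse inequality — simple and exactly testable. Rendering is a
deterministic function of (config, frame index): the per-frame RNG is
seeded with the pair (scene seed, frame index), so scenes round-trip
bit-identically through their JSON manifest.

The calibration defaults to 0.5 μm/px on a 512 × 512 field, chosen so
the 12–67 μm droplets span ~25–134 px and moment-based metrology is not
sampling limited (the source imaging used a 10× objective; its pixel
calibration is unpublished). The recovery AR amplitude of droplet 5 is
clamped so the AR plateau floors at 1 (the tabulated row would
undershoot the spherical endpoint, which no real ellipse can do).

What the generator does **not** emulate: droplet interaction,
aggregation and mass exchange (the analysis explicitly excludes such
droplets), Brownian centroid motion, illumination gradients, defocus
and diffraction at edges, and any physical simulation of the magnetic
stress itself. Passing tests therefore demonstrate correctness of the
measurement chain on clean two-class scenes with known kinetics — not
robustness to optical artifacts absent from the noise model.

## Validation problem sizes

The end-to-end check runs the five-droplet elongation scene with
default noise at 13 frames (0–40 s, denser than the display sampling so
all four parameters are identifiable per droplet) through
enhancement, segmentation, tracking and fitting, and requires each
recovered λ_c to lie within 5% of the generating value; typical errors
are below 1.5%. Fit-recovery checks use 50 random noiseless curves
(λ_c ∈ [3, 20] s, β ∈ [0.8, 3]) sampled at 0.5 s over 0–40 s. Bootstrap
checks use 1000 resamples. These sizes are the package's validation
defaults and are deliberately modest; all scale linearly if enlarged.

## Known limitations

* Touching or overlapping droplets are not split (no watershed); the
  design assumes non-interacting droplets and the generator enforces
  disjoint footprints.
* The mixture model is strictly two-component; scenes with more than
  two intensity classes need a different thresholding stage.
* Identifiability of (λ_c, β) requires the sampled window to cover a
  substantial part of the relaxation; curves truncated well before the
  plateau can trade λ_c against β, which the DE bounds do not prevent.
* The through-origin regression inherits the unpublished pairing of
  diameters with relaxation times; its slope is therefore
  configuration-dependent and is not treated as a reproduction target.
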