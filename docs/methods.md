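# Methods

## The scoring procedure

The analysis unit is a transmission hyperspectral cube of a retinal
wholemount: height × width × 70 bands covering 471–691 nm, one cube per
imaged field, eight fields per retina (four quadrants, each sampled at a
central locus near the optic nerve head and a peripheral locus farther
out; even-numbered fields are peripheral).

Preprocessing runs in a fixed order per cube:

1. *Spatial resize to 20% per axis.* Each output pixel is the
   area-weighted average of the input pixels in its footprint (box
   filter), chosen because the step exists to smooth acquisition noise;
   bilinear resampling is available via `PreprocessParams.interpolation`.
   Output dimensions are floored (2048 × 1536 → 409 × 307); when the
   footprint step 1/factor does not divide the image, fractional edge
   pixels get fractional weight and any uncovered trailing edge is
   truncated. Constant images are preserved exactly.
2. *Anchor normalization.* Each pixel spectrum is divided by the mean of
   its three longest-wavelength band values (685, 687, 691 nm on the
   default grid). Pixels whose anchor mean is ≤ 0 cannot be normalized
   and are flagged degenerate. After this step every retained pixel's
   anchor mean is exactly 1, so the thresholds of the next step are on a
   common scale.
3. *Outlier masking.* A pixel is discarded if **any** of its normalized
   band values exceeds 1.5 or falls below 0. The whole-pixel rule (rather
   than masking individual band values) is used because the downstream
   dot product needs complete spectra; masked categories are tallied
   disjointly (degenerate, then high, then low).

Retained spectra from all cubes are stacked into one matrix with genotype
labels (AD vs CO), mouse and field annotations; row order is manifest
order then row-major pixel order, so stacking is deterministic. The
contrast spectrum `d` is the per-band mean difference between AD and CO
pixel populations with every retained pixel weighted equally, regardless
of how many pixels each mouse contributes (a per-mouse-balanced variant
sits behind `balance_mice=True` for sensitivity analysis). Pixel scores
are `X @ d`; a mouse's score is the unweighted mean over all its retained
pixels pooled across fields — not the mean of per-field means, though
that quantity is reported alongside in `mouse_scores.csv`.

Two scoring modes exist. `in_sample` fits one contrast on all pixels and
scores those same pixels; it is the reference procedure and underlies the
group comparisons, but as a *group-separation estimate* it is
optimistically biased — in fact the in-sample difference of class-mean
pixel scores equals ‖d‖² identically, which the tests verify to 1e-9.
`leave_one_mouse_out` (LOMO) rescoring refits the contrast without the
scored mouse (requires ≥ 2 mice per class) and removes that optimism.

### Calibration caveat of the LOMO t-test

LOMO removes the in-sample bias of the *mean* class difference (on null
cohorts the AD−CO gap is centered at 0 across replicates, which the suite
checks), but the t-test on LOMO mouse scores is **not** calibrated: each
score is dominated by the projection of the shared mean spectrum onto the
held-out contrast, a component that cancels exactly in the class-mean
difference yet drives the within-group variance. The resulting t
statistic is strongly deflated (empirical sd ≈ 0.13 instead of ≈ 1 on
null cohorts), making the test conservative to the point of never
rejecting at the 5% level. Inference on LOMO scores should therefore use
permutation of mouse labels, not the t reference distribution; the
t-test's nominal-level behaviour is asserted in the acceptance suite and
documented there as failing.

## Group statistics

The genotype comparison is the unpaired two-tailed Student t-test on
per-mouse scores with pooled variance, df = n₁ + n₂ − 2 (so 8 vs 8 mice
give df 14 and 8 vs 10 give df 16); Welch's form is available via
`welch=True`. Degenerate zero-variance inputs are reported explicitly
(t = 0, p = 1 for identical constant groups; signed infinite t with a
flag otherwise) rather than as NaN.

Band summaries collapse each mouse to its mean spectrum before computing
per-band group means and t-based 95% confidence intervals — mice, not
pixels, are the independent replicates, and the summary is invariant to
duplicating a mouse's pixels. A pixel-level mode exists for visual parity
with pixel-population plots. Bands where the two CIs are disjoint are
flagged descriptively; no multiple-testing correction is applied across
bands. Whether CIs should be across mice or across pixels was genuinely
open; both are provided and mouse-level is the default on independence
grounds.

The heatmap table arranges field scores as a mouse × field grid with
central/peripheral marginal means; fields without retained pixels stay
absent (NaN), never imputed as zero.

## The synthetic cohort generator

The generator is first-class, tested code: it defines the study
conditions under which the pipeline is validated. Each voxel is

    v(y, x, λ) = B(λ) · A(λ; c) · (1 + ε),   ε ~ N(0, σ²) i.i.d., clipped at 0,

with

- **Baseline** B(λ) = offset + amplitude · logistic((λ − center)/scale):
  a smooth, strictly positive transmission curve rising toward long
  wavelengths (defaults 0.55 + 0.45·logistic((λ−560)/60), unitless
  relative intensity). Its first differences are bounded by
  amplitude·Δλ/(4·scale).
- **Amyloid attenuation** A(λ; c) = exp(−κ·c·(λ_ref/λ)⁴): a
  Beer–Lambert-style exponential with the λ⁻⁴ Rayleigh wavelength
  dependence — the simplest form consistent with scattering by particles
  far smaller than visible wavelengths and with an effect magnitude
  proportional to the burden c. Defaults κ = 0.08 per unit burden,
  λ_ref = 550 nm; with c ≈ 1 this attenuates ~471 nm by ≈ 7% relative to
  the anchor bands after normalization, a realistic subtle effect.
- **Burdens** c ~ LogNormal(ln μ_class, τ) per mouse (τ = 0.3), or
  exactly 0 when μ_class = 0. Presets: `three_month_like` (μ_AD = 0.4,
  effect confined to the shortest wavelengths) and `eighteen_month_like`
  (μ_AD = 1.2, separation extending toward 600 nm); controls carry
  μ_CO = 0. The presets are qualitative by construction — no numeric
  fidelity to any real cohort's spectra is claimed.
- **Spatial gradient**: peripheral (even-numbered) fields carry ρ·c with
  ρ = 1.5 by default; ρ = 1 removes the gradient.
- **Noise**: multiplicative i.i.d. Gaussian, σ = 0.05 per voxel; an
  optional band-correlated illumination drift term (`drift_sd`) is off by
  default. σ = 0 makes cubes exactly B·A.

Determinism: a `SimParams` value fully determines every voxel. The seed
feeds a `SeedSequence`; one child stream draws the burdens and one
further child per cube drives its noise, so cohorts are reproducible
piecewise. Planted out-of-range blocks (for masking checks) overwrite a
`planted_block`-sized tile of the shortest band with 6× the local
baseline, aligned so that downsampling by 1/`planted_block` turns each
tile into exactly one masked pixel.

What the generator does **not** emulate: real tissue texture and vessel
structure (frames are spatially homogeneous apart from noise and planted
blocks), autofluorescence, plaque geometry, focus variation, spectral
correlation of sensor noise, and the true spectral shape of the in-situ
Aβ effect. Passing tests therefore demonstrate that the pipeline recovers
the *assumed* generative signal reliably — correctness of the machinery,
not biological validity on real retinas.

## Problem sizes and numerical choices

Test and acceptance cohorts use 64 × 48-pixel frames (8 mice per class,
8 fields) — the package's scaled stand-in for full 2048 × 1536 sensor
frames, which keeps a 100-replicate power study to about a minute; the
null-calibration study uses 16 × 12 frames over 500 replicates. Frame
size is an ordinary parameter, and nothing in the code depends on these
defaults.

Cubes are stored as float64; the ENVI writer emits full-precision
(`repr`) wavelengths so round-trips are bit-exact. Pipeline CSVs render
floats with 12 significant digits (`%.12g`), making byte-identity of
reruns a meaningful and tested property. Equality tolerances: 1e-12 for
algebraic identities against oracles, 1e-9 where a normalization or
aggregation chain accumulates rounding.

Degenerate inputs are handled explicitly throughout: empty retained-pixel
sets raise before any output is written, single-class matrices name the
missing class, LOMO refuses classes of size 1, and the resize refuses
factors that collapse an axis to zero pixels.

## Known limitations

- The contrast spectrum is the literal per-band mean difference; richer
  discriminant formulations (variance-normalized, multivariate) are out
  of scope by design.
- In-sample group separation is optimistically biased (quantified, not
  corrected), and LOMO t-tests are conservative (see above): hypothesis
  tests on real data should be accompanied by label permutation.
- Irregular wavelength grids are accepted as-is from files; the synthetic
  default is evenly spaced, which real sensors need not be.
- No flat-field or illumination correction beyond anchor normalization,
  no registration or mosaicking of fields, and no per-band (as opposed to
  per-pixel) outlier masking.
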