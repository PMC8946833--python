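# Methods

## Readout and model

The readout is the percentage of γH2AX-positive cells per condition and its
treated/untreated fold change per arm. Positivity is a whole-cell call on a
single per-cell statistic: the brightest background-corrected γH2AX pixel
inside the nucleus mask. This is deliberately not a focus count — one
near-saturating pixel anywhere in the nucleus marks the cell — and it makes
the statistic exactly reproducible from a segmentation plus one image
reduction. The per-experiment threshold is anchored to that experiment's
untreated control, because absolute baselines vary between experiments
(staining, illumination, day effects); fold changes rather than absolute
percentages are compared across experiments for the same reason.

## Pipeline stages and parameters

**Background subtraction** (`segment.subtract_background`): `median`
(default) subtracts a disk-footprint median filter; on 8/16-bit inputs it
uses a sliding-histogram rank filter, which is exact, so a constant
background is removed without residue. `rolling_ball` is available for
ramp-heavy backgrounds. `background_radius` (default 25 px) must exceed the
nucleus radius by enough that the median window at any nucleus pixel is
mostly background (radius ≳ 1.5× nucleus radius); with ~8 px nuclei, 25 px
is comfortably safe. The same method/radius is applied to the signal channel
before scoring unless overridden — symmetric treatment of both channels is
the least surprising default when only one unspecified subtraction step is
called for.

**Segmentation** (`segment.segment_nuclei`): Otsu threshold on the corrected
DAPI image (a fixed threshold is available), 8-connected components,
`min_area` 40 px² to reject debris, border-touching nuclei excluded by
default because a nucleus clipped by the field edge may have its peak pixel
cropped. Touching nuclei can be split by a distance-transform watershed
(`split_touching`); the default is off, since the simulator's default
geometry keeps nuclei separated and whether the original workflows split
touching cells is not knowable — both behaviors are exposed. All-background
images segment to an empty label map, not an error.

**Scoring** (`score.assign_max_signal`): the plain maximum over the mask.
A per-cell percentile (default 100) exists for sensitivity analysis only.
Background subtraction happens before the maximum is taken.

**Classification** (`classify`): the default threshold rule is
`mean + k·SD` (sample SD, k = 2) on the control's per-cell scores — the
standard control-anchored positivity rule, deterministic and robust when the
control contains a small positive baseline. Percentile, Otsu-on-scores and
fixed thresholds are selectable; the method, its parameters and the control
sample size are recorded in every threshold object for provenance. A score
exactly equal to the threshold is negative (strict `>`), consistently
everywhere. Cells are pooled across fields before computing percent positive;
per-field percentages are also emitted.

**Statistics** (`stats`): Grubbs screening is the two-sided single-outlier
test iterated (outliers are removed one at a time and the reduced sample is
re-tested), α = 0.05, with critical value
`G_crit = (n−1)/√n · √(t²/(n−2+t²))`, `t` the upper `α/(2n)` Student-t
quantile with `n−2` df. Iteration never reduces a sample below 3 points —
at n = 3 a significant G is reported but nothing further is removed, since
the test itself needs 3 points. Zero-variance samples are left untouched.
Normality is assessed by Shapiro–Wilk; a significant departure warns but
does not switch the analysis to a nonparametric test, because the planned
comparison is the paired t-test. The paired t-test runs on per-experiment
(control-arm, osmotic-arm) fold-change pairs, two-sided, df = n−1;
zero-variance differences return a flagged degenerate result. Technical
replicates made on the same day should be averaged into one value per
biological replicate before pairing. No multiple-testing correction is
applied. NaCl dose arms can be kept separate (default) or merged via the
pipeline's `arm_pooling` mapping.

**qPCR** (`qpcr`): Livak/Schmittgen workflow with PCR efficiency fixed at 2
(no efficiency correction). Technical duplicates are averaged at the Cq
level before ΔCt; Grubbs screening is applied per gene per condition on the
per-sample ΔCt values.

## The synthetic-data generator

`simgen` emulates the statistical structure the analysis assumes, not the
optics of a microscope. Nuclei are circles with Gaussian radius (mean 8 px,
SD 1 px), placed by rejection sampling with a minimum center separation
(default 24 px, which keeps nuclei disjoint); generation fails loudly,
naming the achievable count, rather than silently dropping cells. The DAPI
channel carries a uniform disk per nucleus; the signal channel carries a
uniform disk at 80% of the cell's peak value with a single brightest pixel
at the cell center. Per-cell peak values are drawn from the negative
(mean 30, SD 8) or positive (mean 180, SD 15) intensity distribution —
separated by many noise SDs, as a usable stain is — and are quantized to the
integer bit grid *before* rasterization, so the recorded `true_peak_signal`
is exactly the brightest background-free pixel of that cell: score-fidelity
checks are equality checks, not tolerance checks. Background is a constant
level (10) plus a planar ramp (amplitude 6) and an optional low-frequency
sinusoid; noise is additive Gaussian (SD 2) with optional Poisson shot
noise, clipped and rounded to the bit range (default 8-bit; 16-bit
supported). Field size and density default to 1024×1024 with 150 cells —
plausible for a 10–20× objective, configurable, and not a claim about the
original acquisitions, which specify none of these.

The experiment generator draws each condition's per-cell positivity as
Bernoulli at `clamp(baseline × factor, 0, 1)`; untreated conditions must
have factor 1, and the default factors (2.4, 4.7 control; 1.2, 1.9 osmotic
on a 0.10 baseline) follow the qualitative co-stress pattern the pipeline
is meant to resolve. `simulate_positivity_experiment` additionally provides
positivity-level simulation (binomial counts, optional log-normal baseline
jitter shared within an experiment) for replicate-level power analysis,
where rendering hundreds of image sets would add runtime but no information:
with well-separated intensity distributions, classification is essentially
error-free and counts are binomial either way.

The qPCR generator inverts the ΔΔCt model: treated-condition Cq equals
control Cq minus the true log2 fold change, the reference gene is
condition-independent, and Gaussian cycle noise (SD 0.15, a typical TaqMan
replicate spread) is added per measurement. Default panel: ATM (−0.5),
ATR (−0.4), PP4 (+0.8), CCDC6 (−1.5) against 18S — directions matching the
H2AX-phosphorylation network biology the assay targets (kinases and the
phosphatase inhibitor down, the phosphatase up under osmotic stress);
magnitudes are round values of realistic size, chosen once.

What the simulator does **not** model: irregular or textured nuclei,
mitotic/multinucleated cells, punctate foci, spatially correlated noise,
optical PSF blur, saturation artifacts, and cell-density gradients. Passing
recovery tests therefore demonstrates that the pipeline's logic is correct
and well-calibrated under its own assumptions — clean blob segmentation,
bimodal intensity mixture, smooth background — not that segmentation would
be this accurate on difficult real micrographs.

## Numerical choices

- All intensity math is floating point; images may be 8- or 16-bit.
- Sample (ddof = 1) standard deviations throughout.
- Percentile thresholds use linear interpolation (numpy default).
- Otsu on an all-constant image is undefined; such images yield zero nuclei.
- Undefined quantities are flagged, not silently dropped: a condition with
  zero cells has NaN percent positive; a fold change over a zero untreated
  percentage is flagged and excluded downstream with a logged reason.
- Determinism: every stochastic step runs off an explicit integer seed
  through `numpy.random.default_rng`; child seeds for experiment fields are
  drawn from the experiment seed in sorted condition order, so outputs are
  byte-identical across runs and independent of dict insertion order.

## Problem sizes in the validation suite

Recovery tests run on simulated fields of 256² (25 cells) for detection and
scoring checks and 512² (150 cells) for positivity and fold-change recovery,
with ≥ 2000 cells per condition in the test suite and ~12000 per condition
in the acceptance script — enough that three binomial standard errors sit
well inside the stated tolerances. Power analysis uses 100 repetitions of 8
replicate experiments at 1000 cells per condition. Grubbs critical values
are cross-checked against a 10⁵-draw Monte-Carlo null.

## Known limitations

- One threshold per experiment is derived from the normal-medium untreated
  control and applied to both arms (a per-arm option exists); if osmotic
  stress itself shifted the whole intensity distribution, per-arm anchoring
  would change absolute percentages (though less so fold changes).
- The nucleus mask approximates the cell; cytoplasmic γH2AX (rare) is
  invisible to the score.
- No mixed-effects modeling of day/plate effects; the paired design absorbs
  shared between-experiment variation but not arm-specific drift.
- Grubbs assumes approximate normality of the screened values; fold changes
  are ratios and mildly right-skewed at small baselines.
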