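# Methods

This note documents the models, conventions and design choices behind
`volvar`, in the spirit of a statistical software methods appendix.

## Measurement model and ratio correction

The unit of analysis is a long-format table with one record per
(participant, scan, run, pre-processing step, ROI), carrying the ROI volume
and the total brain volume (TBV) extracted by that record's own pipeline
step. Step labels (ORIG, RROT, N4BC, N4SS, FS) and ROI labels (LPut, RPut,
LHip, RHip, LMTG, RMTG) are closed vocabularies validated on read: an
unrecognized label raises rather than warns, because a typo would silently
break the factorial structure every downstream test assumes.

All analyses run on the ratio volume/TBV. Each record is normalized by its
own step's TBV — the FreeSurfer brain volume for FS records, the
extraction-mask volume for the registration-based steps — so the correction
is internally consistent per pipeline. Ratios are carried as fractions and
rendered as percentages only in reports.

Before inference the table must be a complete participant × scan × run ×
step × ROI crossing; `validate_crossing` lists missing cells and duplicate
keys, and the analysis entry points refuse partial tables instead of
silently subsetting.

## Percent variability error

For participant i, cell (step j, ROI r), and scans k = 1..n with scan 1 as
reference,

    PVE_jr = 100 · (1/N) Σ_i Σ_{k=2..n} 2|T_i1 − T_ik| / ((T_i1 + T_ik)·(n−1)),

the mean symmetric percent difference between reference and rescan. One
value is produced per (step, ROI) cell. Properties relied on in tests:
scale invariance (any common rescaling of a participant's scans cancels),
the bound 0 ≤ PVE < 200 for positive data, and the n = 2 reduction to the
plain mean symmetric difference. The reference scan index is a parameter
(default 1) for sensitivity checks.

PVE is computed on the TBV-corrected ratios of a single pipeline run
(default run 1). Repeated runs of a deterministic pipeline are
statistically identical, so any run gives the same cell values up to run
noise, which is zero by default; averaging over runs would change nothing
in the default design and would entangle the run axis with the scan axis
when run noise is enabled.

The error band of a corrected ratio X at PVE p% is X·(1 ± p/100). A PVE of
100% or more would give a non-positive lower bound and is rejected. Band
overlap uses the closed-interval convention (touching endpoints overlap);
the boundary case is a measure-zero event for continuous data, so the
choice is cosmetic but fixed. For reporting, the percent bounds are rounded
to 3 decimals first and the mm³ bounds are computed from the rounded
percentages, matching how such bands are quoted in practice.

## Hotelling T² on within-subject contrasts

Each factor is tested by reducing every subject to a contrast vector and
applying the one-sample Hotelling T²:

- **step** (p = 4), **roi** (p = 5), **step × roi** (p = 20): per-subject
  step × ROI cell means, collapsed over scans and runs. Main-effect
  contrasts are differences from the first level in vocabulary order;
  the interaction uses the double differences
  (Y_jk − Y_1k − Y_j1 + Y_11) for j, k ≥ 2.
- **run** (p = n_runs − 1): scan 1 only, cell means collapsed over steps
  and ROIs — algorithmic consistency.
- **day** (p = n_scans − 1): run 1 only, collapsed over steps and ROIs —
  scan-rescan consistency.

T² = n·d̄ᵀS⁻¹d̄ with S the unbiased covariance of the contrast rows. T² is
invariant to any invertible linear transform of the contrast basis, so the
difference-from-first-level choice does not affect the statistic — only the
printed contrast dimension. Two degenerate limits have defined behavior:
an all-zero contrast matrix returns T² = 0 (the exact null of a
deterministic pipeline), and a contrast that is nonzero yet identical
across subjects returns T² = +inf (a certain effect measured without
noise). Any other singular covariance raises.

The critical value follows the one-sample T² law CV = νp/(ν−p+1) ·
F₁₋α(p, ν−p+1) with ν = n − 1 by default — algebraically identical to
p(n−1)/(n−p)·F₁₋α(p, n−p). `hotelling_critical` also accepts an explicit
ν, so a critical value quoted for a given (p, ν) pair can be recomputed
exactly even when the source's ν bookkeeping differs from n − 1.

Effect sizes are generalized eta squared for fully within-subject designs:
SS_effect / (SS_effect + SS_subject + all subject × factor interaction SS),
computed from the exact sums-of-squares decomposition of the subject ×
step × ROI cell-mean array (one-way decomposition for run and day). The
implementation is cross-checked in the test suite against pingouin's
repeated-measures ANOVA to 1e-8. A zero effect SS reports 0 even when the
error SS is also zero (noise-free null); a table with zero total SS is
degenerate and the strict public function raises.

Following a significant omnibus test, seven paired two-sided t-tests
compare steps per ROI (ORIG–RROT, ORIG–N4BC, ORIG–N4SS, RROT–N4BC,
RROT–N4SS, N4BC–N4SS, N4SS–FS; FS is compared only to the step whose
pipeline it most resembles) on per-subject mean ratios, df = n − 1,
significance at the Bonferroni-corrected α/7. Hemispheres are kept as
separate ROI columns, not pooled.

## Mask operations

Probability images are binarized with an inclusive lower bound: voxels in
[threshold, 1] map to 1, reproducing the closed-range mapping of the
standard c3d-style thresholding of warped probabilistic labels. Volumes are
voxel counts times the voxel-dimension product, in double precision with no
rounding. Dice is 2|A∩B|/(|A|+|B|) on the voxel sets equal to one label;
both-empty is an undefined 0/0 and raises, one-empty returns 0. Grids must
match in shape and voxel dimensions (relative tolerance 1e-6); no
resampling is attempted. Orientation metadata is carried opaquely through
NIfTI I/O and never interpreted.

## Synthetic cohort generator

The generator emulates the downstream *measurement structure* of a
stepwise pre-processing study — not images. Its defaults are the study
conditions: 115 participants × 3 scans × 5 runs × 5 steps × 6 ROIs, mean
TBV 1,513,592 mm³ with a 120,000 mm³ between-subject SD (~8%, typical for
healthy young adults), regional fractions of TBV around 0.3% (putamen),
0.22% (hippocampus) and 0.9% (middle temporal gyrus).

Volumes are multiplicative: a per-participant TBV, a stable
per-(participant, ROI) ratio deviation (log-scale SD 0.08), a (step, ROI)
bias factor, scan noise drawn once per scan and shared by that scan's
runs, and run noise drawn per pipeline run (default 0 — a deterministic
pipeline). All noise terms are **mean-one log-normal**, exp(N(−σ²/2, σ²)).
The location shift matters: plain exp(N(0, σ²)) has expectation
exp(σ²/2), and since scan-noise σ differs by step, equal step biases would
still produce a small spurious step effect in the mean; with mean-one
noise, expected volumes depend only on the bias parameters and a no-bias
configuration is exactly null. The shift cancels in the PVE statistic and
vanishes in the noise-free limit.

Scan-noise SDs default to values calibrated cell-by-cell so that expected
PVE spans the 1–3.7% range observed for pipelines of this type, via the
small-σ half-normal relation PVE ≈ 100·(2/√π)·σ (verified by Monte-Carlo
in the test suite before being relied on). Step biases default to 1–4%
shifts with a step × ROI interaction patterned on how rotation,
bias-correction, skull-stripping and FreeSurfer differ across subcortical
and cortical regions; the FS TBV is set 3% tighter than the
extraction-mask TBV. A single root seed drives per-axis substreams, so a
(config, seed) pair reproduces a bit-identical table.

What the generator does **not** model: image intensities, bias fields,
registration deformations, partial-volume effects, motion artifacts,
missing scans, or any participant-level covariates (age, sex). Passing
tests therefore demonstrate the correctness and calibration of the
statistical machinery under the assumed multiplicative log-normal
measurement model, not the behavior of any real pre-processing software on
real scans.

Phantom label images are axis-aligned ellipsoids (voxel v labelled iff
Σ((v−center)/radii)² ≤ 1) on a zero background; perturbation is restricted
to integer-voxel translations so that overlap counts, and hence Dice
values, have exact closed forms.

## Problem sizes and numerical conventions

Simulation-based checks use the smallest sizes at which the quantities
stabilize: 200 participants for noise-recovery checks (sampling error of
PVE ≈ 4% relative), 1000 replicates for type-I calibration (binomial SE
≈ 0.7 percentage points around the nominal 5%), and the full 115-subject
design for single-cohort analyses. Reports render PVE and critical values
at 2 decimals and t statistics at 4; JSON artifacts keep full precision
and are byte-stable for a fixed (config, seed).

## Known limitations

- The generator's noise scales are loosely constrained by published
  variability magnitudes only; real pipelines have heavier-tailed and
  spatially structured errors.
- Between-subject effects (e.g. sex) are out of scope; only within-subject
  factors are tested.
- No sphericity-corrected univariate F alternatives are provided; the
  analysis is deliberately multivariate.
- Dice aggregation across runs is left to the caller; the package computes
  pairwise coefficients only.
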