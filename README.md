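# volvar

Scan-rescan variability analysis for registration-based ROI volumetry.

## The problem

Volumetric MRI studies routinely pre-process T1-weighted scans — rigid
rotation into template space, N4 bias-field correction, skull-stripping —
before segmenting regions of interest (ROIs) and extracting their volumes.
Each step changes the data, and the changes propagate to the measured
volumes. Because group differences of only 1–2% are often read as
biologically meaningful, variance injected by pre-processing can masquerade
as signal. `volvar` implements the statistical machinery for quantifying
this: it separates the contribution of (a) the pre-processing steps,
(b) the scanner (scan-rescan), and (c) the pipeline algorithms themselves
(repeated identical runs), and converts the residual scan-rescan
variability into an error band that should accompany any reported regional
volume.

The package is aimed at neuroimaging methodologists and pipeline
maintainers. It operates on long-format measurement tables (CSV) keyed by
participant × scan × run × pre-processing step × ROI, and on 3D NIfTI label
and probability images. A synthetic-cohort generator with the full study
structure (115 participants × 3 scans × 5 runs × 5 steps × 6 bilateral
ROIs) makes every stage testable without any imaging data.

## The statistics

**Ratio correction.** Every ROI volume is divided by the total brain volume
(TBV) extracted by its own pipeline step, giving a dimensionless fraction
that absorbs head size, hydration and scanner-warmth confounds.

**Percent variability error (PVE).** For participant i with corrected
measurements T_i1, …, T_in across n scans (scan 1 the reference),

    PVE = 100 · (1/N) Σ_i Σ_{k=2..n} 2|T_i1 − T_ik| / ((T_i1 + T_ik)·(n−1))

— the mean symmetric percent difference between scan and rescan. A
corrected volume X with PVE p% should be treated as X ± (p/100)·X when
comparing groups or pipelines; `volvar` computes the band, converts it to
mm³ at a given TBV, and tests whether two bands overlap.

**Repeated-measures Hotelling T².** Each within-subject factor (step, ROI,
step × ROI, run, day) is tested with a one-sample Hotelling T² on
difference-from-first-level contrast vectors: T² = n·d̄ᵀS⁻¹d̄ with critical
value νp/(ν−p+1)·F₁₋α(p, ν−p+1), ν = n−1. Effect sizes are generalized
eta squared (Olejnik–Algina). Significant omnibus effects are followed by
seven Bonferroni-corrected paired t-tests between pipeline steps, per ROI.

## Worked example

Run the full pipeline on the default synthetic cohort:

```bash
volvar report --out demo --seed 7
```

or equivalently from Python:

```python
import volvar
report = volvar.run_pipeline(volvar.SimulationConfig(), "demo", seed=7)
```

The summary (abridged) prints:

```
Percent variability error (scan-rescan, % of the TBV-corrected ratio)
  Step      LPut    RPut    LHip    RHip    LMTG    RMTG
  ORIG      0.96    1.18    1.40    1.19    1.44    1.26
  RROT      1.41    1.39    1.44    1.33    1.60    1.45
  N4BC      1.51    1.54    1.46    1.54    1.52    1.43
  N4SS      3.28    3.10    3.39    3.70    3.66    3.67
  FS        2.62    2.28    2.42    1.84    3.14    2.52

Repeated-measures Hotelling T2
  step       T2 =    7635.7839  CV =  10.08  (p = 4, n = 115)  -> reject
  roi        T2 =   14945.6781  CV =  11.90  (p = 5, n = 115)  -> reject
  step_x_roi T2 =    2131.1221  CV =  40.37  (p = 20, n = 115) -> reject
  run        T2 =       0.0000  CV =  10.08  (p = 4, n = 115)  -> retain
  day        T2 =       1.5727  CV =   6.21  (p = 2, n = 115)  -> retain

Worked error-band example
  N4BC/LHip: ratio 0.215% of TBV, PVE 1.46%
  band 0.212%-0.218% (half-width 0.003%)
  at TBV 1506288 mm3: 3193.3-3283.7 mm3 (range 90.4 mm3)
```

Reading it: scan-rescan noise alone produces 1–3.7% variability in the
corrected regional ratios, largest after skull-stripping (N4SS row). The
omnibus tests detect a step effect and a step × ROI interaction (the
pre-processing steps shift volumes, and shift them differently per region)
while the run effect is exactly zero (the pipeline is deterministic) and
the day effect is retained (the scanner is consistent). The final block
shows the practical consequence: a left-hippocampal ratio of 0.215% of TBV
with a PVE of 1.46% is only known to within about 90 mm³ — a window larger
than many reported group differences.

Individual stages are available as `volvar simulate`, `ratios`, `pve`,
`dice`, `volume` and `analyze`; see `volvar --help`.

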