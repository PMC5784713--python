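# Methods

## The measurement model

`platephen` analyses optical-density time series from arrays of microbial
colonies growing on solid agar, read vertically at 600 nm by an incubating
microplate reader.  Each reading at a well is the sum of the agar's own
absorbance and the absorbance of whatever colony sits above it, capped by the
instrument's hard ceiling of 3.5 absorbance units.  A reading session taken
before any cells are printed provides a per-well agar reference; the colony
signal is then

    A(t) = raw(t) − agar     (per well, per timepoint)

A full-size yeast colony in a 384 array reaches A ≈ 2.5, so usable agar must
stay below ~1.0 or the curve saturates prematurely.  Three empirical quirks
of this measurement inform both the preprocessing and the simulator:

1. **Early dip.** Microscopic bubbles in freshly printed spots act as lenses
   and evaporate over the first hour, producing a transient dip at the start
   of the curve.  Curves can be aligned on their minima
   (`normalize_to_minimum`); the dip is otherwise left in place.
2. **Absorbance-dependent noise.** The SD of successive readings grows
   roughly linearly with the mean reading and is partly synchronised across
   a plate.  `variance_profile` estimates the trend (OLS of per-item SD on
   per-item mean); windowed averaging and the 4-pass "snapshot" protocol
   (`snapshot_average`) are the remedies.
3. **Edge effect.** Perimeter colonies on rich media keep growing after
   roughly 40 h because they see more nutrients; `edge_effect_ratio`
   (perimeter mean ÷ interior mean) quantifies it at a chosen time.

## Timelines and combination

Each reading session is stored with seconds-from-start plus an absolute
start timestamp.  `combine_runs` places all sessions of one plate on a
single timeline measured from the earliest growth session, so continuous
20-minute-interval runs and intermittent snapshot visits combine the same
way.  The agar reference is the mean over the blank run's passes.  Pass
clusters are detected with a gap threshold of 3× the median reading
interval; there is no universally correct rule, but snapshot passes are
minutes apart while visits are hours apart, so any multiplier in a broad
range gives identical clustering.

## Phenotype calculators

Summary values are produced by named calculators in a registry
(`register_calculator` adds new ones):

- `AverageWithoutAgarCalc(window)` — mean A over a closed time window.
  Windowed averaging, not a point estimate, because of noise quirk 2.
- `MaximumWithoutAgarCalc`, `MaxChangeCalc` — plateau proxies; MaxChange is
  the largest rise over the first reading, robust to non-zero printed mass.
- `MaxSlopeCalc` — growth-rate proxy: the steepest OLS slope over sliding
  5-point windows (100 min at 20-min sampling) of the 3-point-smoothed
  curve, reported per hour together with the window-centre "inflection
  time".  Both windows are configurable; the defaults trade noise
  suppression against curvature bias (on a noiseless logistic with
  r = 0.4/h the bias is ≈0.5%, well under the 2% the tests require).  A
  multiphasic warning fires when the window-slope series re-enters the
  band ≥ 80% of its maximum after leaving it — two separated fast phases
  make the single steepest window a questionable rate summary.
- `LagCalc(f)` — first time the smoothed curve exceeds
  printed_mass + f·(plateau − printed_mass), linearly interpolated, with
  f = 0.05 by default.  There is no canonical lag definition for these
  curves; a small fixed fraction of the rise above the printed mass keeps
  the value monotone in f and zero for curves starting above threshold.
  Because lag correlates with printed mass, the runner also emits the
  printed-mass-vs-lag scatter table for inspection.
- `TreatmentRatioCalc(window, ε)` — windowed average under treatment ÷ the
  same under control, per well of a paired ("controlled") experiment.  The
  ratio is suppressed when the control average is ≤ ε = 0.05 absorbance,
  since dividing by a near-blank control is meaningless.  The default
  window is 15–17 h: final-growth discrimination at "~16 h" is read as a
  2-hour averaging window, consistent with the windowed-average remedy for
  high-OD noise.

Negative corrected values are flagged (`negative_corrected`) but never
clipped — clipping would bias printed mass and lag.  Saturated wells (raw ≥
3.5 anywhere) are flagged and retained.  Printed mass is the corrected value
at the single earliest post-print timepoint.

## Cell-count calibration

Absorbance through a roughly cylindrical column is a proxy for a roughly
hemispherical colony, so count grows faster than linearly in A.  The
package ships the two published empirical calibrations

    solid media:   P = 77 900 · e^(1.76·A)
    liquid OD600:  P = 8 000 · (725·A + 7)

plus the hemocytometer formula count = 10 000 · C · (25/S) and the 1:10
dilution rule for liquid readings above OD 1.  `fit_exponential_calibration`
refits (a, b) by unweighted OLS on ln(count) — the spreadsheet-LINEST analog
of an exponential trend fit; because the published fit's convention is not
recoverable, a nonlinear least-squares alternative on the raw count scale is
available via `method="nls"` for sensitivity analysis.  `bland_altman`
compares two prediction methods with the standard bias ± 1.96·SD limits of
agreement.

## QTL mapping

The mapping stage targets haploid biallelic crosses with tetrad structure
(four spores per meiosis, 2:2 segregation) and biological replicates kept as
separate rows for power.

- **Genotype probabilities.**  At every position of a 1-cM pseudomarker
  grid (markers plus a regular grid, per chromosome), the probability of
  carrying allele 1 is computed from a two-state Markov chain with Haldane
  recombination fractions r = (1 − e^(−2d/100))/2, conditioning on the
  nearest *observed* flanking markers per individual; one observed flank
  uses the single transition probability, none gives 0.5.
- **LOD.**  Regression of phenotype on the probability vector
  (Haley–Knott-style): LOD = (n/2)·log10(RSS0/RSS1).  For a haploid cross
  with dense markers this is numerically very close to EM interval mapping
  and is deterministic and fast; with p ∈ {0,1} it is exactly the
  two-group ANOVA LOD (tested against that oracle).
- **Significance.**  Phenotypes are permuted only within strata defined as
  tetrad × replicate group, so a sample can never exchange values with its
  own biological replicate, and each replicate plate is shuffled
  independently.  The threshold is the ceil((1−α)(n_perm+1))-th order
  statistic of the genome-wide maximum LOD over n_perm permutations
  (defaults n_perm = 1000, α = 0.05 → the 951st of 1000).  Under the null
  this yields a type-I rate of (n_perm+1−k)/(n_perm+1) ≈ α, which the test
  suite verifies empirically at 200 datasets × 200 permutations.
- **Peaks and intervals.**  Local maxima above the threshold are reported
  with 1.5-LOD support intervals: the contiguous super-threshold run around
  the peak expanded by one grid position on each side (first drop-below
  positions included), clipped at chromosome ends.  Peaks whose intervals
  overlap merge into one QTL, keeping the higher peak.  Across crosses,
  overlapping intervals merge transitively into distinct regions
  (`merge_regions`), so region count ≤ QTL count.
- **Interchange.**  `export_rqtl_csv` writes the standard R/qtl "csv" cross
  layout (phenotype + A/B genotype codes under marker/chromosome/cM header
  rows) and `read_rqtl_csv` reads it back.

## The synthetic-data generator

`simulate_curve` draws raw(t) = min(agar + A0 + K/(1+e^(−r(t−tm))) −
dip·e^(−t/τ) + noise, 3.5) with noise SD = σ0 + σ1·signal and an optional
plate-synchronised per-timepoint component.  Defaults — K = 2.0, r = 0.4/h,
tm = 12 h, A0 = 0.1, dip 0.05 over τ = 0.3 h, σ0 = 0.01, σ1 = 0.02, agar
0.5 — describe a healthy yeast colony on rich media reaching plateau within
a day, noise of a few hundredths at low OD rising to ~0.05 at plateau, and
an agar layer well below the 1.0 usability limit.  `simulate_plate` adds an
optional diagonal agar-thickness gradient (a poorly mixed plate), small
per-well agar jitter, and a post-40-h linear perimeter boost for the edge
effect.

`simulate_cross` builds tetrads as two independent meiotic products plus
their allele-flipped complements — the simplest construction with exact 2:2
segregation and marginally Haldane-consistent recombination (no chiasma
interference, no gene conversion).  Phenotypes are baseline + Σ effect·g +
Gaussian noise; a 1-SD additive effect at balanced allele frequencies
explains ~20% of phenotypic variance.  Defaults follow the 24-tetrad, 96-
segregant, 2-replicate design with ~20-cM marker spacing.

What the generator does **not** emulate: colony morphology, flocculation,
non-logistic stress responses (death-phase declines, delayed second growth
phases beyond the synthetic biphasic fixtures), genotyping error, and
segregation distortion.  Passing tests therefore demonstrate correctness of
the computations under the stated measurement model, not robustness to
every pathology of real plates.

## Problem sizes used in the checked examples

The test suite and worked examples run on a 96-well plate with 24 strains ×
2 replicates over 24 h of 20-min readings, and on crosses with 2 chromosomes
× 100 cM at 20-cM marker spacing (n = 192 phenotype rows).  The type-I
calibration uses 200 null datasets × 200 permutations; the power benchmark
25 datasets × 100 permutations; recombination checks use 5000 simulated
meioses.  These sizes give Monte-Carlo error comfortably inside the asserted
tolerances while keeping the whole suite under a minute.

## Known limitations

- The published supplementary measurement tables (paired cell counts, the
  six-cross paraquat dataset, the bacterial curves) are not redistributable
  here; the reproductions that need them look under `data/external/` and
  fail with an explanatory message otherwise.  The code paths they exercise
  are covered by synthetic equivalents.
- The exponential-calibration fit convention (log-linear vs raw-scale) is
  genuinely ambiguous; both are implemented and agree on noiseless data but
  can differ on heteroscedastic real data.
- The inflection point is defined operationally (centre of the steepest
  window), not as a fitted model parameter, since these curves resist
  parametric logistic fits.
- Proprietary reader export formats are out of scope; the canonical CSV
  dialect plus the parser registry is the supported ingestion path.
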