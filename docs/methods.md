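# Methods

`lipidims` re-implements, as a tested pipeline, a comparative MALDI-TOF
lipidomics analysis of cerebral white matter in a murine second-hand
cigarette-smoke exposure model: the same tissue is measured both as a lipid
extract spotted on a steel target (high-throughput modality) and by imaging
mass spectrometry (IMS) of tissue sections, summarized here as one mean
spectrum per region of interest.  The analysis asks three questions: which
lipid ions each modality detects and how the two detection sets overlap;
how the shared ions' relative abundances compare across modalities; and how
each ion's abundance trajectory responds to smoke exposure duration and
withdrawal.

## Study design and the synthetic generator

The emulated design has four exposure groups — air control for 8 weeks
(A8), cigarette smoke for 4 or 8 weeks (CS4, CS8), and 8 weeks of smoke
followed by 2 weeks of recovery (CS8+R) — with 6 replicate animals per
group, each measured in both modalities (48 sample cells).  No raw spectra
from the original study are available, so every downstream stage is
exercised against a synthetic-data module whose defaults *are* the printed
design:

| parameter | default | meaning |
|---|---|---|
| `n_extract_ions` / `n_ims_ions` / `n_shared` | 83 / 62 / 25 | ions detectable per modality and jointly (120 distinct) |
| `mz_range` | 600–1300 Da | analysis window for lipid ions |
| `n_replicates` | 6 | animals per group |
| `recovery_fraction` | 0.60 | persistently suppressed ions planted with partial/full recovery |
| `isotope_prob` | 0.20 | chance an ion carries a C13 satellite (+1.00335 Da); matches 5/25 flagged shared ions |
| `isotope_ratio_range` | 0.3–0.6 | satellite/monoisotopic intensity ratio; lipids of 40–50 carbons have first-isotope ratios near 0.45 |
| `sigma_log` | 0.15 | replicate lognormal intensity jitter (log-scale SD); kept multiplicative so intensities stay positive |
| `noise_sd` / `baseline_level` | 1.0 / 5.0 | additive Gaussian baseline noise over a flat offset (arbitrary units) |
| `peak_sigma` / `grid_step` | 0.05 / 0.01 Da | Gaussian peak width and profile grid spacing |
| `min_ion_separation` | 0.6 Da | exceeds 2 × the 0.25 Da match tolerance, so matching on planted data is unambiguous |

Modality bias is implemented as piecewise sampling weights over three m/z
bands (600–700, 700–800, 800–1300 at the default range): shared ions are
drawn mid-range, IMS-only ions mostly from the high band, extract-only ions
from the low/mid bands.  This reproduces, qualitatively, the observation
that imaging favours high-m/z ions while extracts are rich in mid-range
ions.

Each ion carries a response category drawn from a configurable mix
(defaults: 15% stable; 20/20/10% inhibited sustained/progressive/transient;
15/10/10% stimulated sustained/progressive/transient) and group multipliers
drawn with margins of at least ~2 group-mean noise SDs from the
classifier's default decision boundaries, so planted categories are
recoverable at the default noise.  "Stable" ions (internal-control
analogues) carry all multipliers equal to 1.

### Compositional balance

Total-ion-count (TIC) normalization makes every downstream intensity a
*relative* abundance: a fold change survives normalization exactly only if
the group's total ion current equals control's.  The generator therefore
interprets planted multipliers as effects on relative abundances and
projects the drawn base intensities (least squares with positivity
clipping) onto the subspace where each non-control group's intensity-
weighted mean multiplier is exactly 1, satellites included.  Without this
constraint a planted "stable" ion would drift by the group's net TIC shift
— the same compositional caveat that applies to any TIC-normalized
experiment.  Panels for which no positive balanced assignment exists
(effects all one-signed) are redrawn.

### What the generator does not emulate

No spatial pixel rasters, laser or matrix physics, mass-calibration drift,
peak-shape asymmetry, correlated (chemical) baseline noise, ion
suppression, or missing replicates.  Passing tests therefore demonstrate
the correctness of the analysis logic under the declared noise model, not
robustness to instrument artefacts absent from it.

## Preprocessing

Peak picking levels each profile trace by its median, estimates noise as
1.4826 × the median absolute deviation of the levelled trace, takes strict
local maxima above `snr_threshold` (default 3) times that noise, and
centroids each by the intensity-weighted mean m/z over ±0.1 Da; reported
intensity is the levelled apex height.  On pure white per-bin noise the
strict-maximum rule admits a small false-positive residue (~0.14 peaks/Da
at SNR 3, none at SNR 5, measured over 100 seeded traces); these
non-recurring peaks are removed downstream by replicate-consensus
filtering, so the default threshold favours sensitivity.

Each replicate peak list is TIC-normalized (intensities sum to 1), then
replicates of a group/modality are fused by single-linkage clustering of
pooled peaks within 0.25 Da: each replicate contributes at most its most
intense peak per consensus ion; consensus m/z is the mean of contributing
peaks; consensus intensity averages over all replicates with absent
treated as zero (so it reflects abundance *and* detectability; a
detections-only mean is available by flag); clusters present in fewer than
half the replicates (`min_frequency` 0.5) are dropped.  Normalization
precedes aggregation because TIC is a per-spectrum quantity.  With
chained peaks the consensus m/z can drift beyond the tolerance from an
extreme member; the planted minimum separation precludes this on
generated data.

## Cross-modality comparison

Matching pairs the control-group (A8) consensus lists of the two
modalities greedily by ascending |Δm/z| within a 0.25 Da tolerance, ties
toward the lower-m/z extract peak, each peak used once.  The tolerance
absorbs the 0.1–0.15 Da discrepancies between the reference table's
printed m/z values and the higher-precision variants quoted in text (both
are stored in the bundled table).  Greedy matching agrees with the optimal
(minimum-total-|Δm/z|) assignment on all well-separated instances and on
~99% of dense unstructured random instances (bounded in tests).

C13 satellites are flagged when a peak sits 1.00335 ± 0.1 Da above a more
intense partner (`max_ratio` 1.0 — a first isotopologue cannot exceed its
monoisotopic peak in this mass range).  Flagged satellites are excluded
from detection counts and matching by default: they are annotations of
their monoisotopic parent, not distinct lipid species.  Detection counts
(total, per-modality, shared, modality-only) therefore refer to distinct
species; the identities total = extract + IMS − shared and
tallies-partition-shared are enforced before any output is written.

Shared-ion concordance uses the signed percent difference of IMS vs
extract normalized intensity, `100·(IMS − extract)/extract`, mapped onto
five categories with half-open intervals: |pct| < 10 → "=", 10 ≤ |pct| <
50 → ">"/"<", |pct| ≥ 50 → "≫"/"≪" (boundaries land in the
larger-difference class; a 1e−9 slack absorbs float fuzz on exact-ratio
inputs).  The bundled 25-ion reference table ships as package data with
its printed tallies (5 "=", 12 extract-higher, 8 IMS-higher) asserted in
the suite; per-ion intensity realizations of the table are synthetic
stand-ins, drawn inside each category's interval with a 2-point margin
off the boundaries.

## Multivariate stage

Heat-map statistics operate on the ions × groups matrix of group-mean
normalized intensities.  Rows are z-scored with the sample-SD (n−1)
convention (constant rows become zero with a warning), then clustered
agglomeratively under Euclidean distance.  Complete linkage is the
default — the distance, not the linkage, is what the source analysis
names, and complete linkage is the common heat-map default; single and
average linkage are available.  Ties break deterministically toward the
lexicographically smallest cluster-id pair, so dendrograms are
reproducible; the merge sequence is verified against a naive O(n³)
re-agglomeration oracle and scipy cophenetic distances in the suite.
Dendrogram cuts into k groups sever the k−1 final merges; k is
user-supplied (the observed 6 imaging / 12 extract "main groups" are
descriptive, with no stated cut criterion, and are not targets).

PCA runs on the samples × ions matrix, column-centered and by default
unit-variance scaled (peak intensities span decades; toggleable), via
singular value decomposition.  Scores, orthonormal loadings and
explained-variance fractions are checked against an independent
eigendecomposition and scikit-learn to 1e−8.  The run summary reports,
per modality, the ratio of each smoke group's centroid distance from
control to the mean within-group spread on the first two components;
on default synthetic studies this ratio is far above 1 (groups separate),
asserted across seeds rather than per seed.

## Response-pattern taxonomy

Each classifiable ion (positive mean in all four groups) is assigned one
cell of a three-axis taxonomy from its group-mean trajectory, in log-fold
space relative to A8 so classification is scale-invariant:

* **direction** — inhibited / stimulated / unchanged, testing the CS8/A8
  (falling back to CS4/A8) fold against a symmetric no-change band of
  `change_threshold` (default 1.25-fold; boundary folds count as changed);
* **progression** — transient if the CS8 fold is back inside the band;
  progressive if the CS8 effect exceeds CS4's by more than
  `progress_threshold` (default 1.15-fold); sustained otherwise;
* **recovery** — full if CS8+R is inside the control band; partial /
  paradoxical if it moved toward / away from control beyond the
  progression threshold; none otherwise.

The source describes these effects qualitatively ("sharply reduced",
"progressive decline") with no numeric cutoffs; the default thresholds are
configurable and serialized into output metadata.  Classification uses
group means (matching averaged-data figures); per-replicate testing is a
non-goal, and no hypothesis testing or multiple-testing correction is
performed.

The headline *suppressed recovery fraction* is the share of persistently
suppressed ions — inhibited with sustained or progressive progression —
classified partial or full recovery.  Transiently inhibited ions are
excluded from this denominator: they have already returned to control
levels before withdrawal, so "recovery after withdrawal" is vacuous for
them (and their mechanical recovery = full would otherwise inflate the
fraction).  The summary also reports the all-inhibited-denominator
variant, since the published 60% figure's denominator is ambiguous.
Diagnostic-ion calls split shared ions into exposure-responsive
(|CS8/A8| fold ≥ `responsive_fold`, default 2.0) and stable internal
controls (all folds within `stable_band`, default 1.25); the thresholds
must nest so the sets are disjoint.

## Numerical choices and determinism

All randomness flows from one integer seed through named substreams
(panel, per-spectrum, table realization), so identical configs produce
byte-identical outputs, asserted in the suite.  Decision boundaries use a
1e−12 (folds) or 1e−9 (percent) slack so boundary cases are stable
against unit-last-place noise.  Degenerate inputs fail loudly: empty or
all-zero peak lists cannot be normalized, single-column matrices cannot be
z-scored, out-of-range dendrogram cuts and over-rank PCA requests raise,
ions with zero control mean are routed out of fold-based classification.

## Problem sizes

The default acceptance computation runs one zero-noise study (48 spectra
of 70 001 points) for the detection counts and 20 seeded default-noise
studies (~500 suppressed imaging ions pooled) for the recovery fraction;
the whole script completes in well under a minute per study on one CPU.
Oracle-backed tests use small instances (≤ 10 peaks per side for optimal
matching, 8 × 5 matrices for the O(n³) clustering oracle) where exhaustive
verification is cheap.

## Known limitations

Raw-format ingestion (Bruker .d, imzML rasters, mzML) is out of scope; the
pipeline starts from plain-text profile spectra or peak lists.  The
replicate noise model is a stand-in, not an estimate — the source reports
no replicate-level variance.  The compositional (TIC) caveat above applies
to any real dataset processed with this pipeline: fold changes are
relative abundances, and a large one-sided shift in total signal will
masquerade as opposite-direction changes in unaffected ions.  Recovery
subcategories sit closer together than the direction/progression axes
(the "none" band spans only ±the progression threshold around the CS8
fold), so at the default noise their per-cell fidelity is inherently lower
than the ≥95% achieved by the direction × progression cells.
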