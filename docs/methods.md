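# Methods

This note documents the models, parameters and design choices behind the
pipeline, and what the synthetic benchmark does and does not establish.

## Units and conventions

Flow-cytometer channels (FSC_A, SSC_A, GFP) are in instrument arbitrary
units (a.u.), meaningful only relatively; all fluorescence analysis is
on the log10 scale (a threshold of 2.36 log10 a.u. and 236 a.u. are the
same cut).  Optical density (OD) is in absorbance units; volumes in µl.
The per-well fluorescence statistic is the **mean of log10 GFP** over
gated events; the alternative (log10 of the arithmetic-mean GFP) is
available via `statistic="log_of_mean"` — for tightly log-normal wells
the two differ by a nearly constant offset (σ² ln10 / 2 in log10 units),
so the choice rarely changes a classification, but the default is the
statistic that per-replicate histograms and the threshold are defined
on.  GFP values below 1 a.u. (including non-positive compensated values)
are clamped to the floor before the log transform.

## Gating

An event is kept iff `fsc_min ≤ FSC_A ≤ scatter_max` and
`ssc_min ≤ SSC_A ≤ scatter_max`.  The upper cut defaults to 900,000
a.u.: scatter saturates well below the instrument ceiling of 1,048,575
a.u., and saturated events carry no size information.  No authoritative
lower cuts exist for this assay, so the defaults (10,000 a.u. on both
channels) are deliberately conservative, configurable, and stated
explicitly wherever results depend on them.  Wells with fewer than
10,000 gated events are not retained.  Gating is idempotent and
monotone in its bounds; both are tested.

Whole plates can be excluded through a curated list.  An optional
heuristic (`flag_abnormal_plates`, off by default) proposes candidates
whose positive-control median log GFP falls below 3.0 log10 a.u. — a
screening aid, not a replacement for curation.

## Threshold calibration

The wrong-direction cost (README) is piecewise linear in t with
derivative (#pos below t − #neg above t)/N, which is non-decreasing, so
the cost is convex and its minimum is attained on an interval whose
endpoints are control values.  `optimize_threshold` evaluates the cost
at every distinct control value, takes all breakpoints within 1e-12
(relative) of the minimum, and returns the midpoint of the spanned
interval plus the interval itself.  Tie-break by midpoint is symmetric
and reproducible; with perfectly separated controls the interval is the
whole gap between the highest negative and lowest positive well.  The
denominator counts control **wells** (the unit of analysis throughout);
it is constant in t, so the argmin is unaffected by that reading, only
the reported cost value.

## Correctness

A well mean exactly at the threshold classifies as high (a disclosed
convention; the optimizer's midpoint tie-break makes exact ties
measure-zero in practice).  Replicates are pooled across growth
conditions by default, with a standard-conditions view (T=30 °C,
H=16 h, SC medium) available.  Shading: green strictly above 90%
correct, gray strictly below 50%.  Circuit score = min over the four
input strains; when an input fails in the majority of wells, the
majority-vote truth table is matched against the six gates and the two
constant functions to name the effective Boolean function.  NOR00 is
simultaneously the positive control and the NOR-gate 00 strain, so the
24-strain summary includes it and excludes only WT.

## Scatter bimodality

2-means (k-means++, 10 restarts, fixed seed) on unstandardized
(log10 FSC_A, log10 SSC_A) — both axes are log a.u. of the same
instrument, so no rescaling is warranted.  Cluster 1 is deterministically
the cluster whose center has the higher SSC/FSC ratio, making labels
stable across runs and event orders.  The regression quantity is the
Pearson r of log10 SSC_A on log10 FSC_A, per cluster and pooled: when
two lobes offset across the within-lobe trend are pooled, r is strongly
attenuated, so per-cluster r values each exceeding the pooled r is the
signature of genuine bimodality.

The bimodality flag uses the mean silhouette of the 2-means split
computed in **whitened** coordinates (centered, decorrelated, unit
variance), on a 2,000-event subsample.  Whitening is essential: the raw
silhouette of a split through a single elongated (highly correlated)
Gaussian is deceptively high (~0.5), whereas after whitening any
unimodal Gaussian scores ≈0.31 and offset lobes score well above;
the flag threshold is 0.40.  A single planted cluster therefore never
flags, which is tested.

## Plate reader

`dilution_plan` interprets the protocol's "1:100" as culture:*total*
(1 part culture + 99 parts media), the only reading under which OD 1.0
dilutes to exactly 0.01; culture:media 1:100 would give 0.0099.  Growth
correlations are Pearson's ρ of initial vs final OD, pooled or grouped,
with groups under 3 records or constant vectors reported as NaN and
negative correlations flagged as anomalous.  The cross-modality check
regresses plate-reader bulk GFP on final OD × 10^(mean log10 GFP) — the
per-cell fluorescence on the **linear** scale, since bulk fluorescence
is additive over cells — and flags wells beyond 3 residual SDs.  Raw
plate-reader values are taken as-is (no blank subtraction by default).

## DNAseq verification

Presence = at least one read containing the gRNA sequence or its
reverse complement as an exact substring (a minimum-hit count is
configurable for noisy data).  Reads with ambiguous bases simply fail
to match at those positions; non-ACGT characters in a gRNA are an
error.  Matching raw reads cannot distinguish a gRNA coding sequence
from its identically-sequenced promoter target site, so the design
matrix ORs the two roles.  Strains with no read data are flagged as
missing rows, never zero-filled.  Anomalies: design 1 / results 0 is an
unexpected absence (build error or coverage gap); design 0 / results 1
an unexpected presence (mislabeling, design error, contamination).
Design compatibility requires every design-required gRNA to be observed
(strict mode also forbids extra observed parts).  Coverage = total read
bases / genome size (12 Mb for yeast).

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume;
its defaults are fixed study conditions, not tuning knobs.

* **Campaign shape**: runs of 93 sample wells on a 96-well plate
  (3 positive + 3 negative control wells, the rest experimental strains
  in a rotation continuing across runs), positions randomized per plate;
  30,000 events per well.
* **Scatter**: mixture of two bivariate log10-normal lobes (means
  (5.20, 5.50) and (5.55, 5.20), SD 0.18, within-lobe correlation 0.92,
  weights 0.4/0.6) plus 5% debris (log-mean (3.8, 3.6), SD 0.35).  All
  channels hard-clipped to [0, 1,048,575] a.u.  The lobe offsets run
  across the within-lobe trend, reproducing the qualitative pattern that
  per-cluster regressions far exceed the pooled fit; the debris model
  and the specific lobe positions are fixtures, not measured claims.
* **GFP**: per-cell log10-normal around a *well-level* mode: low 1.4,
  high 3.4 log10 a.u. (a two-log band gap whose midpoint ≈2.4 sits near
  the expected threshold), well-level mode jitter SD 0.10, per-cell SD
  0.15.  Failures are whole-well: with a per-strain probability the
  entire well expresses the wrong mode.  This keeps every per-replicate
  SD far below 0.613 log units — replicate-level bimodality with tight
  wells, the regime the analyses are designed for.
* **Growth**: final OD = od_max·raw/(raw + od_max) with raw =
  target OD · 2^(hours/doubling time) (doubling 1.5 h, od_max 2.0,
  16 h), times log-normal noise (SD 0.05); increasing in target OD with
  diminishing returns.  A per-well "vigor" factor (log-normal, SD 0.3)
  multiplies both the post-recovery OD and the final OD, giving the
  weak positive initial/final coupling seen in pooled growth data.
* **Plate reader**: bulk GFP = gain (0.01) × final OD × mean per-cell
  GFP × log-normal noise (SD 0.05).
* **Reads**: 200 reads of 100 nt per strain, random background with
  each present gRNA (20 nt, from a deterministic synthetic library
  r1–r12) embedded in 5 reads at random positions/orientations.
  Injected anomalies drop or add parts relative to the design.  The
  real gRNA sequences and part lists are user-supplied inputs; the
  synthetic wiring scheme (per-gate part sets, input signals r7/r8,
  reporter r10) is a fixture.
* **Reproducibility**: one seed fans out through named SeedSequence
  substreams per plate layout, well and strain, so datasets are
  byte-identical under a fixed seed and adding a well never perturbs
  existing ones.

**What passing tests show — and don't.**  The generator is log-normal,
clip-clean and anomaly-exact by construction.  Passing end-to-end tests
demonstrates that the pipeline recovers planted parameters under the
assumed structure (whole-well failures, two-log band gap, exact reads);
it does not establish robustness to spectral spillover, doublets,
drifting instrument gain, partial-well failures, sequencing errors, or
the unpublished lower scatter gates of real archived data — analyses of
such data must treat the gates and plate-exclusion list as tunable
inputs.

## Benchmark scenario and problem sizes

The benchmark campaign uses 4 runs × 78 wells (24 strains × 12
replicates + 24 control wells) × 30,000 events ≈ 9.4 M events — large
enough for per-strain binomial checks at 3 SDs while a full run
(simulate → gate → calibrate → score → scatter → plate reader → DNAseq)
completes in well under a minute.  Planted failure rates (NAND11 0.58,
NOR11 0.50, OR01 0.60, OR10 0.90, XOR01 0.70, XNOR11 0.33) and DNAseq
anomalies (OR strains carrying AND-like parts; XOR strains missing
r1/r9 and the r6 input) emulate the failure modes such replication
campaigns surface — an OR that scores as an AND, an XOR observation
compatible with none of its candidate designs — and are fixed scenario
constants.

## Known limitations

* FCS 3.x ingestion is not implemented; the ingestion path reads the
  CSV/TSV dialect the generator writes, with configurable channel names.
* No spectral compensation, doublet discrimination (FSC_H/FSC_W) or
  MEFL bead calibration.
* No alignment/assembly in DNAseq verification — exact matching on raw
  reads only, with the coding-sequence/target-site ambiguity noted
  above.
* Condition-effect statistics are out of scope; conditions are pooled
  or filtered, never tested.
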