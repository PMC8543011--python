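# Methods

`tilreact` implements an analysis workflow for identifying tumor-specific
reactive tumor-infiltrating lymphocytes (TILs) across three data modalities:
flow cytometry of short co-culture activation assays, paired bulk RNA-seq of
TILs stimulated with autologous vs allogeneic tumor cells, and single-cell
RNA-seq of TILs in fresh tumor tissue. This note records the models, the
conventions, the parameters that matter, and the design choices made where
the underlying protocol leaves the analysis open.

## Flow-cytometry reactivity analysis

### Reactivity definitions

Events are live T cells of one subset (CD8+ or CD4+). Positivity is called
per channel against a scalar cutoff (strictly greater than; an intensity
exactly at the cutoff is negative). CD137 is detected on two channels —
surface (S-CD137) and intracellular (IC-CD137) — and total CD137 (T-CD137)
is the Boolean OR of the two calls. Three union metrics are reported, each
as a percentage of live subset events minus the matched unstimulated
("TILs alone") control:

* **CD137+** — positive for T-CD137;
* **Antitumor Function+ (AF+)** — positive for at least one of TNF, IFNγ,
  CD107a;
* **Total Reactive** — positive for at least one of all four markers.

Pre-subtraction, Total Reactive ≥ AF+ ≥ each single cytokine/degranulation
marker by construction; the suite asserts this monotonicity.

### Gate thresholds

The source protocol gates manually; `set_thresholds` replaces that with a
reproducible rule: the cutoff for each activation channel is a high quantile
(default 0.999) of the unstimulated control's intensity distribution, so at
most 0.1% of control events are called positive per channel. This rule
presumes the control's genuine background positivity is below 1 − quantile;
if a control contains more true positives than that, the quantile climbs
into the positive population and the gate should be placed explicitly
(the quantile is configurable, and cutoffs can be supplied directly through
`GateThresholds`).

The viability dye is bimodal (dim live cells, bright dead cells), not
tail-distributed, so its cutoff defaults to the midpoint of the control
range rather than a quantile; it can be set explicitly. Live gating is
applied before any metric. CD4/CD8 assignment uses mutually exclusive gates
on the two lineage channels; double-positive and double-negative events are
excluded.

### Background subtraction and clamping

Reported percentages are stimulated minus control. Negative differences are
converted to 0.01% and values exceeding 100% after normalization are
converted to 100%; every reported background-subtracted percentage therefore
lies in [0.01, 100]. The 0.01% floor applies to reported percentages only —
internal combination shares are floored at 0 before renormalization, so a
combination genuinely absent from a sample reports share 0, not a floor
artifact.

### Combination profiles and contribution decomposition

Boolean gating of (T-CD137, TNF, IFNγ) yields 8 combinations; the
all-negative one is excluded and the remaining 7 are reported as fractions
of the reactive pool. Each combination's percentage of the parent population
is subtracted against the matched control combination before renormalizing
(a flag switches to union-level subtraction only). The coarser three-way
grouping — CD137+AF−, CD137−AF+, CD137+AF+ — is computed over cells positive
for at least one panel marker, with AF including CD107a when measured.

"Order of relevance" for the contribution decomposition is decreasing
single-marker positive fraction, with ties broken by the fixed panel order
(CD137, TNF, IFNγ, CD107a). The k-th marker's gain is the number of events
it newly adds to the union of the first k−1, as a percentage of the total
union; gains are non-negative and sum to 100%.

### Inhibitor modulation

Protein-transport inhibitors (Brefeldin A, Monensin) shift where CD137 is
detectable. Modulation is reported as condition/reference ratios against the
no-inhibitor condition, with percent modulation (ratio − 1) × 100, per CD137
form (surface, intracellular, total).

### Paired testing

Per-sample percentages are compared with the two-sided paired Wilcoxon
signed-rank test (exact null distribution for small, tie-free samples;
all-zero differences return p = 1 by convention). Gene-level differential
expression uses the paired t-test (below).

## Paired bulk expression and activation gene sets

Expression is log2-normalized per sample (default: total-count scaling to a
common library size, then log2(x+1); both steps configurable — under
proportional scaling the choice cancels out of paired differences). The
per-patient log2 fold-change (LFC) of a gene is its autologous-condition
value minus its allogeneic-condition value; the per-gene summary is the
arithmetic mean LFC and a two-sided paired t-test across patients. No
multiple-testing correction is applied by default, mirroring the raw
p < 0.01 filter convention; genes with zero difference everywhere get p = 1.

Activation gene sets keep genes with p < 0.01 and mean LFC above a
subset-specific cutoff — 2.0 for CD8+ TILs, 1.4 for CD4+ — and always
exclude the three assay markers *TNFRSF9*, *TNF* and *IFNG*, since the sets
are meant to act as an independent proxy of activation. Validation against a
reference ranking reports the fraction of set members within the top K
(default 300) genes by mean LFC (stable sort, gene-name tiebreak) and the
fraction with reference mean LFC > 1.

## In situ single-cell classification

Cells are called positive for a marker gene when expression exceeds a
threshold, default 0 — i.e. any detected expression. This suits deep
full-length (Smart-seq2-like) data where detection tracks expression; for
shallow droplet data a higher cutoff is advisable, hence the parameter. The
2^3 combinations of (*TNFRSF9*, *TNF*, *IFNG*) define 8 functional clusters,
grouped by the number of positive markers into Triple Negative / Single /
Double / Triple Positive; the two specificity markers (*ENTPD1*, *ITGAE*,
encoding CD39/CD103) define 4 clusters, and an 8 × 4 cross-tabulation links
the two partitions.

Heatmaps show, per gene (or per signature panel), the per-cluster mean
expression standardized across clusters to mean 0 / SD 1 with the population
(n) denominator — the Z-score is across clusters, not across cells, so a row
reads as "where is this gene high". Genes constant across clusters get an
all-zero row; empty clusters are dropped with a logged warning, never
imputed. Panel scores are the per-cell mean of normalized (per-cell total
scaling + log1p) expression over the panel's genes; panel gene lists
(exhaustion/dysfunction, co-stimulation, effector, naïve) are user-supplied
inputs.

## Synthetic data generators

The generators exist so every estimator in the package can be scored against
known latent truth. Their defaults encode the in vitro composition the
workflow was built around, fixed once:

* **Flow events** (`FlowSimConfig`). Each event has a subset (60% CD8) and a
  latent functional class — one of the 2^4 positivity combinations of
  CD137/TNF/IFNγ/CD107a. The stimulated (autologous) CD8 mixture is 41%
  reactive, with within-reactive combination shares chosen so that CD137
  covers 74% of the reactive pool, the CD137-only combination is 21%, and
  the CD137/AF sub-grouping is 21/26/53; the CD4 mixture is 29% reactive
  with TNF covering 84% and sub-grouping 5/69/26. CD107a defaults to
  all-negative (its marginal contribution is negligible in this assay).
  Control conditions (allogeneic, alone) contain only all-negative cells.
  Channel intensities follow a two-component Gaussian location–scale model
  on an arcsinh-like scale (negative N(0.5, 0.35), positive N(3.5, 0.5));
  no per-event intensity data exist for the real assay, so this shape is a
  stand-in and nothing downstream depends on it beyond component
  separation. Non-reactive cells stain spuriously positive per marker at
  `background_rate` (default 0.02%, the order of typical ICS control
  background) in all conditions, so control subtraction cancels it in
  expectation; the default deliberately stays below 1 − gating-quantile so
  the quantile gate lands between components. CD137+ cells are
  surface/intracellular positive with occupancies (0.90, 0.65); inhibitors
  multiply the occupancies (e.g. BFA: surface × 0.24, intracellular × 1.32)
  while conserving total CD137 — the model relocates detection rather than
  destroying it, so simulated total-CD137 modulation is 0 where the real
  assay shows small nonzero shifts. 3% of events are dead (bright
  viability).
* **Paired bulk** (`BulkSimConfig`). Gene baselines N(6, 2) on log2 scale,
  patient offsets N(0, 0.3), per-sample residual SD 0.5, 12 patient pairs,
  2,000 genes of which 60 are spiked at LFC 3 — effect and noise sizes at
  which a well-powered paired design should recover essentially all spikes.
* **Single cell** (`SCSimConfig`). 10,000 cells per subset across the 8
  marker classes (40% Triple Negative, 30% single-, 15% double-positive,
  15% Triple Positive). Marker counts are 1 + negative binomial in positive
  cells and exactly 0 otherwise, so positivity is identifiable before
  dropout; dropout zeroes any count with a configurable probability
  (default 0). Fifty activation genes follow a negative binomial whose mean
  doubles per positive marker (log2 step 1.0) — the monotone gradient the
  heatmap analyses should recover; 200 background genes are flat. *ENTPD1*
  positivity is coupled to *TNFRSF9* (65% vs 12%), *ITGAE* independent at
  35%. Counts are zero-inflated negative binomial in spirit; real
  Smart-seq2 data are TPM-like, so the package standardizes on counts and
  normalizes downstream.

What the generators do **not** emulate: spectral spillover/compensation,
doublets, batch effects, TCR structure, ambient RNA, and cluster-specific
library-size variation. Passing recovery tests therefore demonstrates the
estimators are correct under the stated statistical structure, not that the
workflow is robust to those real-data artifacts.

## Numerical conventions and degenerate inputs

* Positivity boundary: strictly greater than the cutoff, everywhere
  (channels, marker-gene expression).
* Percent floor/cap: 0.01 / 100, applied to reported subtracted values.
* Z-score rows: population (n) denominator; constant rows → 0.
* Paired tests: all-zero differences → p = 1; zero-variance nonzero paired
  shifts → p = 0 (t-test).
* Ties: contribution ordering by fixed panel order; top-K ranking by stable
  sort with gene-name tiebreak.
* Empty subsets, empty controls, empty clusters (< 2 non-empty), unmatched
  patients, K beyond the gene universe, and marker-gene name collisions all
  raise configuration errors naming the offending input.
* Determinism: every generator consumes a single `numpy` Generator seeded
  from its config; identical config + seed reproduces outputs byte-for-byte
  (asserted on serialized tables), and the pipeline manifest records config,
  version and output checksums so a run is reproducible from the manifest
  alone.

## Problem sizes

Recovery suites run at the sizes the guarantees are stated for: 50,000
events per seed (10 seeds) for combination-fraction recovery, 20 replicates
of 2,000 genes × 12 pairs for gene-set recovery, 2,000 null genes for t-test
calibration, and 10,000 cells for gradient recovery — sizes chosen to make
binomial/multinomial error bands tight relative to the effects being
checked while keeping the full suite fast on a single CPU.

## Known limitations

* The quantile gate is a stand-in for expert manual gating; it assumes
  well-separated populations and a nearly clean control.
* Inhibitor effects conserve total CD137 by construction; small real shifts
  in total detection are not modeled.
* Expression-based positivity at threshold 0 is not appropriate for sparse
  droplet scRNA-seq without adjustment.
* The package derives gene sets from whatever paired cohort it is given; it
  does not ship the original cohort's gene lists, which are not public.
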