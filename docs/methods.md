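# Methods

This note documents the models and procedures implemented in `ripnet`, the
synthetic study that exercises them, the parameters that matter, and the
numerical choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. The analysis chain

The pipeline reconstructs, stage by stage, how the loss of a dominant
neuronal miRNA propagates through a differentiation time course:

1. **Binding-site calling** (`ripnet.peaks`) on AGO2-RIP per-base coverage.
2. **Target filtering** (`ripnet.targets`): genes with WT-specific 3'UTR
   AGO2 signal ∩ genes up-regulated in the knockout ∩ an annotated-target
   list.
3. **Signed wTO networks** (`ripnet.wto`) over TF nodes, per condition and
   day, with bootstrap link probabilities.
4. **Differential network classification** (`ripnet.codina`) of WT vs
   knockout links into common/different/specific.
5. **SOM trajectory clustering** (`ripnet.som`) of persistently DE TFs.
6. **Atlas correlation profiling** (`ripnet.atlas`).
7. **miRNA normalisation, takeover detection, activity ranking**
   (`ripnet.mirna`).

### Binding-site model

A candidate region is a maximal run of nonzero depth — the simplest
deterministic starting point consistent with contiguous read pile-ups.
With region summit *S* and thresholds (τ = 10 reads, f₁ = 0.20,
f₂ = 0.05):

* *S* < τ ⇒ the whole region is background.
* Cut every base with depth strictly below f₁·S (ties stay inside sites).
* A sub-site is eligible for recursion when its own summit ≥ max(f₁·S, τ);
  eligible sub-sites are recursively split at f₂ of their *own* summit, and
  maximal uncut stretches are emitted.

Because a first-pass cut leaves no base below f₁·S ≥ f₂·(any sub-summit),
the f₂ recursion only ever separates structure introduced at deeper
levels; in practice it preserves weak shoulders attached to a site, which
is its purpose. Two consequences are load-bearing and tested: emitted
summits never fall below τ, and re-splitting an emitted site returns it
unchanged (idempotence). The linear threshold-cut reading (rather than a
bidirectional walk from the summit) is an interpretation; the brute-force
oracle in the tests implements the same contract independently.

Consensus requires ≥ 1 shared base with a site in *every* other replicate
(no reciprocal-fraction rule); WT-specific sites are WT consensus sites
with no knockout overlap. Site signal entering gene-level summaries is the
replicate-mean depth summed over the site, so per-condition comparisons are
mean-based. Genes with zero whole-cell expression get an undefined
normalised signal and are excluded downstream rather than imputed.

### Differential expression

The built-in DE stage is a Welch two-sample test on log2(count + 1) with
Benjamini–Hochberg adjustment across genes — intentionally simple, since
the stage is a pluggable interface that accepts any external table in the
`(gene_id, log2fc, pvalue, padj)` schema. Negative-binomial shrinkage
models are deliberately out of scope. Zero-variance degenerate groups are
resolved by direction: equal means give p = 1, unequal means p = 0.

### Signed wTO

For nodes *i, j* against the background of all expressed genes,

ω_ij = (Σ_{u≠i,j} a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − |a_ij|),
k_i = Σ_{u≠i} |a_iu|,

with Pearson *a*. The sums run over every expressed gene except the pair
itself — including fellow node-set members (the alternative, background
only, differs by one term and is not recoverable from the method's prose).
|ω| ≤ 1 holds by construction and is verified on 10⁴ random structures.
Zero-variance genes get all correlations set to 0 with a warning.

Expression filtering keeps a gene when its replicate-mean RPKM reaches the
floor (default 5) in at least one condition/day group — a gene is removed
only when it is below the floor on *every* day. The boundary (exactly 5.0)
is kept.

The bootstrap resamples sample columns with replacement within each
condition/day group (networks are built per day per condition, so samples
are exchangeable replicates). The link probability is the two-sided
zero-crossing rate p = 2·min(#{ω\* ≤ 0}, #{ω\* ≥ 0})/B, an interpretation
of "probability of the relationship being random"; retention is p ≤ 0.10.

**Known calibration limit.** On independent Gaussian data at the study's
replicate depth (7 samples, B = 200) the retained fraction of null links
measures ≈ 0.12 rather than 0.10: the discrete bootstrap p at B = 200
includes the boundary atom, and the percentile zero-crossing bootstrap is
anticonservative for this statistic at n = 7 (the same implementation
becomes conservative at larger n — ≈ 0.057 at 30 samples, ≈ 0.043 at 60).
The acceptance script reports the measured fraction; no correction is
applied because the uncorrected rule is the documented procedure.

### Differential network classification

Per comparison, each network's weights are scaled by its own max |ω| so the
distance filter is scale-free across networks of different density. A link
present in all networks with one sign is α; a sign change across networks
is β; presence in exactly one network is γ (with > 2 networks, presence in
a strict sign-consistent subset is also treated as specific). β requires
an actual sign change between *present* links — a sign against an absent
link is γ. The kept set is links with ‖w̃‖/√N > 0.5. The richer geometry
of the full published classifier (sub-categories of specificity) is
reduced to these three categories plus the distance filter, which is all
the downstream analysis consumes.

Node calls use a χ² goodness-of-fit of the node's kept-link category
counts against uniform thirds (df = 2); significant nodes get their modal
category, ties and non-significant fits are "undefined". Expected counts
below 5 are flagged (`low_expected`) but still tested, as no small-degree
rule is part of the procedure.

### SOM trajectory clustering

Input trajectories are per-day log2 fold changes of TFs significant on
every day 1–4, z-scored per day across the selected TFs ("normalized fold
changes" is otherwise undefined; the z-score makes days comparable).

The map is a batch SOM on a rectangular grid with Gaussian neighborhood,
radius decaying linearly from half the larger grid dimension to 0.3 (the
final epochs are therefore essentially nearest-prototype mean updates),
codebook initialised along the first two principal axes (linear
initialisation avoids dead units on small grids). The grid grows along
1×2, 1×3, 2×2, … (most-square factorisation by unit count); each larger
grid is trained both fresh and warm-started from the previous codebook
plus the worst-fitted trajectories with Lloyd refinement, keeping the
better fit. The warm start guarantees the average distortion (mean
squared member-to-prototype distance) is non-increasing along the growth
path, which the stopping rule presumes. Growth stops at the first grid
whose average distortion falls below the cut; per-unit q-errors are
reported but not individually thresholded.

**Distortion cut.** The cut is scale-dependent. On the z-scored nFC scale
a trajectory has unit variance per day (total ≈ 4 for a 4-day course), and
the fold-change estimation noise leaves a residual well below 0.1 per
trajectory; `ripnet.evaluation.NFC_DISTORTION_CUT = 0.2` (several times
the noise floor, far below the ≥ 0.3 left by any merged-cluster solution
of this geometry) is used throughout the analysis. The pipeline default
remains 10, the published value on its original (non-z-scored) scale; both
are exposed as parameters.

Cluster summaries smooth the member-mean trajectory with a
shape-preserving local cubic (PCHIP) — at the handful of observed days
available, this is the faithful small-n limit of a local-regression
smooth: it interpolates the cluster mean at the days, reproduces linear
trends exactly, and cannot introduce spurious non-monotonicity.

### Atlas profiling

Top DE genes of day *t* vs day 0 within one cell line are ranked by padj,
ties broken by |log2fc| then gene id (deterministic even on degenerate
input). Both query and atlas are log2(x+1)-transformed before Pearson
correlation (standard variance stabilisation). A (region, age) call is
significant when its r exceeds the mean r of the *other* regions at the
same age by more than twice the SD of r among similar-age columns —
"similar age" is fixed as the age ± one ordered neighbor and exposed as a
window parameter. The rule is applied to correlations (not raw expression
means); that reading of an ambiguous prescription is deliberate and
flagged here. Merging regions averages their columns at shared ages and
carries single-coverage ages through.

### miRNA quantification

Counts are divided by each sample's housekeeping mean (arithmetic mean;
geometric vs arithmetic is not specified anywhere, and the arithmetic mean
is the plainer reading), making values invariant to lane depth.
Abundance is strict: raw counts > 200 in at least one sample. Takeover
candidates are the three-way intersection of abundance with knockout
up-regulation in both AGO2-IP and whole-cell counts; the DE stage runs on
raw counts (count-scaled inputs suit the log2(x+1) test; the tables are
depth-matched by construction), while normalised counts feed the density
and activity summaries. Activity is IP / whole-cell signal per miRNA;
species with zero whole-cell signal are excluded from that condition's
ranking with a warning; ranks are unique within condition (descending
activity, ties broken by id).

## 2. The synthetic study

`ripnet.synthio` generates every input with a recorded ground truth. One
master seed drives independent named RNG streams (CRC-derived), so each
table is reproducible bit-for-bit and generators can be regenerated
independently.

Design (defaults):

* **Pileups** — 60 regions × 1000 bases, 3 replicates per condition,
  Poisson(0.5) background. Planted sites are isoceles triangles (height
  40, width 61) whose linear flanks make the 20%/5% thresholds land at
  analytic positions: 20 WT-only sites inside the 3'UTRs of the planted
  target genes, 20 condition-shared sites, and boundary decoys at heights
  8–12 that straddle the 10-read rule.
* **Expression** — 300 genes × (2 conditions × 5 days × 7 replicates).
  Six TF modules (5 TFs + 15 member genes each) load on a per-sample
  latent factor (TF loading 0.6, member loading 2.0, log-normal noise
  σ = 0.10 log2), giving within-module |r| > 0.9. Module 0 is rewired in
  the knockout from day 1 by sign-flipping two TFs' loadings (β links);
  module 1 is silenced (γ links); the planted rewired-link set is the 16
  affected TF pairs. Modules carry three DE trajectory shapes (rising /
  falling / early-transient, scaled by effect size 1.5 log2) so all 30
  TFs are persistently DE with high power. 20 target genes get a
  +1.5 log2 shift in the knockout from day 1. 30 genes sit below the
  RPKM floor on every day. Both conditions are exchangeable at day 0.
  Raw counts are negative binomial (dispersion 0.05) around RPKM × 10;
  RPKM carries log-normal noise — the standard overdispersion convention.
* **miRNA tables** — 40 species + 5 housekeeping rows, 2 conditions × days
  {0, 4} × 3 replicates (12 samples). The dominant species ramps to ~80%
  of WT counts at day 4 and is zero in the knockout throughout; 3 takeover
  species triple in knockout whole-cell counts and gain an extra 1.5× IP
  loading. Each species has a fixed RISC affinity (geometric series,
  ratio 1.15) applied identically in both conditions, so the activity
  ranking reflects species identity rather than counting noise.
* **Atlas** — 5 regions × 8 ages; each region follows a smooth random age
  drift; one designated block is the WT day-4 mean profile plus noise.

### What the generator does not emulate

Read-level artifacts (mapping bias, multi-mappers, GC effects), gene
length variation in RPKM, mean–variance trends across expression,
batch/library-size confounding, overlapping or nested transcripts,
unbalanced designs, and any real biological annotation. Recovery results
on this data therefore demonstrate the *correctness and statistical
behaviour of the chain under its stated model* — planted effects of
published magnitude are recovered at the published thresholds — not
performance on real sequencing data, where effect sizes, noise and
annotation error are less favourable.

## 3. Parameter defaults

| Parameter | Default | Meaning |
|---|---|---|
| τ (background) | 10 reads | summit floor for binding sites |
| f₁ / f₂ | 0.20 / 0.05 | summit-fraction split thresholds |
| DE α | 0.05 | BH-adjusted significance level |
| B | 1000 | bootstrap resamples per network |
| p-cut | 0.10 | bootstrap retention probability |
| RPKM floor | 5 | expressed-gene background filter |
| r-min | 0.9 | TF–gene correlation for gene sets |
| Φ distance cut | 0.5 | kept-link normalized distance |
| χ² α | 0.05 | node category call |
| n-top | 1000 | DE genes for atlas correlation |
| count floor | 200 | miRNA abundance threshold |
| SOM cut | 10 (pipeline) / 0.2 (z-scored nFC) | distortion stopping rule |

## 4. Problem sizes

The bundled study (60 regions, 300 genes, 30 TFs, 70 expression samples,
B = 1000 over 10 condition-day networks) is sized so the full pipeline
runs in a few seconds and the complete acceptance computation — including
the 200-repeat null calibration and 10⁴ bound trials — in well under a
minute on one CPU, while keeping every planted effect at the magnitudes
described above.

## 5. Known limitations

* The bootstrap link probability is anticonservative at 7 replicates
  (§ signed wTO); downstream results are protected by the CoDiNA distance
  filter, which discards the weak spurious links this admits.
* The splitter contract fixes one reading of an under-specified published
  procedure (linear threshold cuts; strict-inequality cutting; ties kept).
* χ² node calls at low degree violate the usual expected-count ≥ 5 rule;
  they are flagged rather than suppressed.
* The two-SD atlas rule is applied to correlations; with very few regions
  per age the SD estimate is coarse.
* `de_test` is a screening test, not a count model; for real data plug in
  a dedicated DE table.
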