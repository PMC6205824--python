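# ripnet

Dissecting the regulatory consequences of losing a dominant neuronal miRNA
(a miR-124-like species) during induced neurogenesis, from AGO2-RIP binding
signal and transcription-factor co-expression networks.

When a highly expressed miRNA is knocked out, three things happen at once:
its direct targets lose AGO2 (RISC) binding in their 3'UTRs and rise in
expression; other miRNAs take over part of the silencing load; and the
transcription-factor network downstream is rewired over the differentiation
time course. `ripnet` implements the complete analysis chain that separates
these effects, exercised end-to-end on a bundled synthetic-data generator
with planted ground truth, so every stage's recovery can be measured
exactly.

The package is aimed at computational biologists who want a tested,
reusable implementation of this pipeline — binding-site calling by
recursive summit splitting, expression-normalised target filtering, signed
weighted-topological-overlap (wTO) networks with bootstrap link
probabilities, differential network classification, SOM trajectory
clustering, developmental-atlas correlation and miRNA activity ranking —
rather than a one-off collection of scripts.

## The methods at the core

**Binding sites by recursive summit splitting.** Within each candidate
region (maximal run of nonzero read depth) with summit *S*: regions with
*S* < 10 reads are background; the region is cut wherever depth falls below
0.20·*S*; each emerging sub-site whose own summit clears both that cutoff
and the 10-read floor is recursively split at 0.05 of its own summit, which
preserves weak shoulders. Only sites present in **all** replicates are
kept; WT-specific sites are those with no overlapping knockout site. Per
gene, 3'UTR site signal is normalised by whole-cell expression.

**Signed weighted topological overlap.** For TF nodes *i, j* embedded in
the background of all expressed genes (RPKM ≥ 5 on at least one day), with
*a_xy* the Pearson correlation and *k_i* = Σ_{u≠i} |a_iu|:

    ω_ij = ( Σ_{u≠i,j} a_iu · a_uj + a_ij ) / ( min(k_i, k_j) + 1 − |a_ij| )

so |ω_ij| ≤ 1 and a strong link needs the two TFs to agree with the whole
transcriptome, not just with each other. Link significance is the
bootstrap zero-crossing probability p = 2·min(#{ω\*≤0}, #{ω\*≥0})/B over
B = 1000 column resamples; links with p > 0.10 are dropped.

**Differential networks.** Comparing the WT and knockout networks per day,
each link is **α** (present in both, same sign), **β** (sign change) or
**γ** (one network only); weights are scaled per network by max|ω| and a
link is kept when its normalized distance ‖w̃‖/√N exceeds 0.5. Nodes are
assigned the modal category of their kept links when a χ² goodness-of-fit
against uniform thirds rejects at p < 0.05.

**Trajectories, atlas, miRNA activity.** TFs differentially expressed on
every day 1–4 are clustered on their per-day z-scored log2 fold changes by
a batch SOM whose grid grows until the mean squared member-to-prototype
distance falls under a cut; top day-*t*-vs-day-0 DE genes are correlated
against a region × age atlas with a match called when r exceeds same-age
regions by > 2 SD of similar-age correlations; nCounter-style miRNA counts
are housekeeping-normalised per replicate, species > 200 raw counts in ≥ 1
sample count as abundant, and RISC activity = IP / whole-cell signal is
ranked within condition.

## Worked example

The numbered drivers under `analysis/` run the whole study (seed 7) and
print what they find; intermediate files go to `scratch/run/`, summary
records to `results/`:

```
$ python analysis/01_simulate.py
  n_planted_sites: 40
  n_planted_targets: 20
  n_planted_diff_links: 16
  ...
$ python analysis/02_call_binding_sites.py
WT consensus sites: 54; WT-specific: 22; planted WT-site recall: 20/20
$ python analysis/03_filter_targets.py
high-confidence targets: 20 (precision 1.00, recall 1.00)
$ python analysis/05_differential_networks.py
rewired-link recall (union over days 1+): 16/16
$ python analysis/06_som_trajectories.py
30 persistently DE TFs on a 1x3 grid (distortion 0.043); ARI vs planted shapes: 1.00
$ python analysis/07_atlas_profiling.py
significant (region, age) calls: [('region3', 5)]; planted block: ('region3', 5); best r = 0.995
$ python analysis/08_mirna_activity.py
takeover candidates: ['miR-002', 'miR-003', 'miR-004'] (planted: ['miR-002', 'miR-003', 'miR-004'])
```

Reading the output: all 20 planted miRNA targets pass the three-way
intersection (WT-specific 3'UTR site ∩ up in knockout ∩ annotated) with no
false positives; all 16 planted rewired TF links surface among kept β/γ
links; the SOM recovers the three planted trajectory shapes exactly; the
atlas query resolves uniquely to the block it was built from; and the three
miRNAs planted as taking over silencing load are identified exactly.

The same pipeline runs from a shell via the `ripnet` CLI (`ripnet all
--seed 7 --outdir out/`, or per-stage subcommands), and each stage is an
importable function for use on real bedGraph / TSV inputs.

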