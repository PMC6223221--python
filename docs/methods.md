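# Methods

## Scope and model

`methregions` quantifies DNA methylation sub-patterns around protein-coding
genes in stage-structured whole-genome bisulfite (WGBS) data and relates
them to gene expression. The analysis unit is one chosen transcript per
gene; its ±20 kb neighbourhood is partitioned into 12 named regions and its
promoter (TSS ± 2 kb) into 20 consecutive 200 bp bins. All coordinates are
0-based half-open (BED convention); the TSS of a `+` strand gene is
`tx_start` and of a `-` strand gene `tx_end`, and every flank/bin layout is
mirrored in the direction of transcription.

### Transcript selection

From a refFlat/BED12 table, only mature-mRNA accessions (prefix `NM_` by
default, configurable) are kept, and of transcripts sharing a
(gene, TSS) pair only the lexicographically smallest accession survives —
a deterministic tie-break with no biological weighting.

### The 12 regions

Upstream flanks `up2/up5/up10/up20` cover 0–2/2–5/5–10/10–20 kb upstream of
the TSS; downstream flanks `down2..down20` mirror them from the TES
(`down2` starts at the TES itself). The gene body splits into `5UTR`
(TSS→CDS start in transcript order), `exon` (exonic bases within the CDS
span), `intron` (the CDS-span complement of exons) and `3UTR` (CDS
end→TES). For coding genes these four tile `[tx_start, tx_end)` exactly;
for non-coding genes 5'UTR/exon/3'UTR are emitted empty and `intron` holds
the intra-gene gaps, so the body is deliberately not fully tiled there.
Defining the UTRs as whole genomic spans (rather than exonic bases only)
keeps the 12 labels a partition, at the cost of counting UTR-intron bases
as UTR; this is a documented convention, not a claim about splicing.
Flank regions are not trimmed against neighbouring genes: a CpG inside two
genes' neighbourhoods contributes to both.

### Promoter bins

Bin *k* (k ≥ 1) is `[TSS + (k−1)·200, TSS + k·200)` along transcription;
bin −*k* mirrors it upstream. There is no bin 0; bin 1 is the first 200 bp
downstream of the TSS and bins −4..6 jointly span −800..+1200 bp. Bins
overhanging a chromosome end are clipped and flagged `partial`.

## Aggregation

CpG calls are read per sample (standard 5-column or Bismark-coverage
dialect), rows with methylation outside [0, 1] are rejected and counted,
coverage below `coverage_min` (default ≥ 5) is dropped, and `−` strand
calls are then collapsed onto the `+` strand C of the dyad by a
coverage-weighted mean (`collapse_strands`, default on). Because filtering
precedes collapsing, a dyad whose individual strands are under-covered is
discarded even if its pooled coverage would pass; this matches the
per-call reading of the coverage rule.

A region's level is the **unweighted arithmetic mean** of the levels of
the covered CpGs inside any of its intervals; a region with no covered
CpG is missing, never zero. Stage values average the replicates that are
present; the genome-level value is the unweighted mean over genes (not
CpG-weighted). Whole-gene methylation pools every CpG across the 12
regions (CpG-weighted across labels), which equals the plain mean over the
gene's covered neighbourhood CpGs. Aggregation uses per-chromosome binary
search over position-sorted calls with a prefix sum of levels; a
brute-force interval scan is kept as a test oracle (agreement to 1e-12).

## States and transitions

Methylation fractions are discretised as hypo (≤ `hypo_max`), hyper
(≥ `hyper_min`) or moderate, both boundaries inclusive; missing values stay
unclassified. No consensus thresholds exist for whole-gene WGBS levels, so
the defaults 0.3/0.7 are conventional cut-offs, configurable and echoed
into every output header. Transition tables count genes classified at both
stages of a pair (3×3 over states); unclassified genes are excluded and
reported. The pipeline tabulates consecutive stage pairs plus every
pre-implantation stage against the final (post-implantation) stage.

## CpG density

CpGs per bin are counted by the + strand C position (half-open bins).
Classes per 200 bp window: LCG < 4 CpGs, ICG 4–8, HCG > 8 — a total,
monotone step function. The promoter-level roll-up (one class per gene) is
the class of the per-gene maximum bin count by default (`mean` available):
a promoter is as CpG-rich as its densest window; the alternative averages
density over the whole ±2 kb.

## Expression integration

RPKM are log2-transformed after zero-reset: zeros are replaced by the
minimum non-zero RPKM, per sample by default (`global` available) —
per-sample is preferred because sequencing depth makes detection floors
sample-specific. For every stage and every region/bin, Pearson r is
computed across genes with both stage-averaged methylation and
stage-averaged log2 expression present; r is withheld when fewer than
3 genes remain or either vector is constant. The bins × stages matrix of r
is summarised by PCA (feature-centred, unscaled — r values are already
commensurate) with a deterministic sign convention (largest-magnitude
loading positive).

## Differential filtering at bin 1

Four filters between stages A (default: penultimate, ICM) and B (default:
last, post-implantation): (i) replicate-mean bin-1 methylation decreased
more than `fold_change_min`-fold (default 2; the direction of change is
configurable because either demethylation or de-novo methylation can be
the event of interest); (ii) Welch two-sample t-test p < `p_max` — the
default 0.5 is deliberately permissive, letting the fold-change criterion
dominate (0.05 is the conventional choice);
(iii) the gene's stage-A level exceeds the cohort mean at stage A;
(iv) expression increased A→B. Genes with fewer than two replicates in
either stage are flagged untestable; whether they may still pass is a
policy switch (default: fail). Setting `fold_change_min=None` disables
filter (i) so a fully vacuous configuration exists for sanity checks. The
selected identifiers are written one per line for external GO tools; the
enrichment itself is out of scope.

## Synthetic data generator

The generator is first-class, tested code and defines the study
conditions under which recovery is demonstrated.

* **Geometry.** `n_genes` (default 500) three-exon coding genes, random
  strand, lengths 3–8 kb, placed with ≥ 40 kb gaps so ±20 kb
  neighbourhoods never overlap; ~10% of genes get a decoy transcript (an
  `NR_` non-coding twin or an alternative `NM_` sharing the TSS) to
  exercise transcript selection. The chromosome is auto-sized (~24 Mb at
  500 genes) unless given; an infeasible explicit length is an error.
* **CpG landscape.** Per promoter bin, CpG counts are Poisson around a
  unimodal profile `1 + 11·exp(−(x−0.5)²/(2·2.5²))` (x = bin midpoint in
  bins): peak 12 at bin 1, ~1 at the tails, qualitatively giving HCG bins
  near the TSS and LCG bins at the upstream edge. Background CpGs occupy
  even positions outside promoters at a mean spacing of 100 bp. The
  written genome is an AT background with CG planted exactly at these
  positions, so a FASTA scan recovers them bit-for-bit.
* **Methylation design.** Each CpG carries a design mean per stage:
  promoter-core CpGs (−800..+1200 bp of the TSS) take a hypo level
  (default 0.12, rising to 0.25 post-implantation); 3'UTR CpGs a hyper
  level (0.85); planted subsets override their genes (see below). All
  remaining CpGs take a per-stage background solved in closed form so the
  cohort's **expected** gene-level mean equals the requested global
  trajectory (default 0.50, 0.35, 0.33, 0.32, 0.30, 0.30, 0.75 across
  zygote → post) — without this calibration the fixed zones and planted
  subsets would bias the global mean. Observed levels are beta draws
  around the design mean (SD 0.05 default; 0 = noise-free); coverage is
  negative binomial (mean 30, dispersion 5) so the ≥ 5 filter bites; 10%
  of CpGs are reported on both strands to exercise dyad collapsing.
* **Expression coupling.** A per-gene latent z drives log2 RPKM
  (3 + 1.5 z + N(0, 0.3)); CpGs in up2/promoter-core/5'UTR receive −c·z
  and 3'UTR CpGs +c·z, with c chosen analytically so the designed Pearson
  r magnitude (0.3) is realised given the per-gene zone scatter (SD 0.08).
  2% of RPKM values are zeroed (never for planted differential genes) to
  exercise the zero-reset rule.
* **Planted subsets.** 50 genes are set to 0.10 across all
  pre-implantation stages and 0.90 post (whole neighbourhood): designed
  hypo→hyper transitions. 30 further genes have bin-1 levels 0.60 (ICM) →
  0.20 (post) and a +2 log2 expression shift at post: designed to pass all
  four differential filters. Both subsets are recorded in the ground-truth
  JSON together with the realised expected global means.

### What the generator does and does not emulate

It reproduces the *structure* real data would show — stage trajectories,
zone contrasts, density profile, correlation signs, replicate noise,
coverage dropout — but not linkage between neighbouring CpGs, partially
methylated domains, CpG-island annotation, copy-number or mapping
artefacts, or biological covariance between stages. Passing recovery tests
therefore demonstrates that the estimators are unbiased and correctly
wired under the designed conditions, not that real embryonic methylomes
meet those conditions.

## Numerical choices and problem sizes

Half-open interval logic throughout; means use pooled sums (no Welford
needed at these sizes); beta parameters are guarded by clipping design
means to [0.02, 0.98] and capping the SD at 0.45·√(μ(1−μ)). Output tables
are TSV with `%.6g` floats and sorted `# key=value` headers, making
repeated runs byte-identical under a fixed seed.

Recovery suites run at the designed scale of 500 genes: stage-mean
recovery and noisy transition recovery on one 3-replicate dataset;
zero-noise transition recovery with a single replicate (noise-free draws
make replicates redundant); the correlation-sign study over 100 single-
replicate datasets with background CpG spacing widened to 300 bp and no
planted subsets (they are irrelevant to that estimand). At 500 genes the
designed bin-1 density peak exceeds its neighbours by ~4 standard errors
of the per-bin mean, so peak localisation is asserted there; at the
60-gene unit-test fixture only unimodality is asserted, since the contrast
is within Poisson noise at that size.

## Known limitations

* Non-coding genes break the four-way body partition by design; their
  exonic bases belong to no region.
* Promoter bins and flank regions overlap (up2 coincides with bins
  −10..−1), so a CpG can contribute to one region and one bin; region and
  bin tables are therefore reported separately, never summed.
* The Welch t-test is meaningless with single replicates; such genes are
  only selectable under the explicit `untestable_policy="pass"`.
* Correlations are computed gene-wise per stage; no multiple-testing
  correction is applied because the r values are descriptive, not tested
  hypotheses.
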