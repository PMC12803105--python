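# Methods

## Scope and data model

The package implements the computational path from mapped iCLIP cross-link
events to prioritized target genes for a repressive, 3'UTR-binding RBP, plus
the statistics used to validate targets in reporter and overexpression
experiments. Upstream read processing (trimming, demultiplexing, mapping) is
out of scope: the entry points are a cross-link site table (BED6, one
nucleotide per record, score = supporting read count) or alignments (SAM),
together with gene models (GTF), 3'UTR sequences (FASTA), a differential
expression table and annotation tables (TSV). All internal coordinates are
0-based half-open; GTF is converted at the I/O boundary; strand-aware
sequence extraction reverse-complements minus-strand intervals.

## Cross-link sites

Each mapped, stranded read contributes one event at its 5'-terminal aligned
position shifted by `offset` in the 5' direction. The default `offset=-1`
follows the iCLIP truncation convention (reverse transcription stops one
nucleotide downstream of the cross-linked base); `offset=0` places the event
exactly at the read terminus. Both are exposed because published analyses
differ on this point; the choice shifts every coordinate uniformly and does
not affect any downstream statistic.

## Permutation-FDR peak calling

For one gene with sites at positions `p_i`, scores `s_i`, and total events
`n = Σ s_i` over the gene span `[start, end)`:

- window height `h_i` = summed score within ±`window` nt (default 3),
  inclusive;
- null: the `n` individual events (not the sites) are redistributed
  uniformly over the genomic span, `n_perm` times; each permutation consumes
  exactly one `rng.integers(start, end, size=n)` draw, which makes the
  stream trivial to replay in an independent oracle;
- for each observed height `h`,
  `FDR(h) = mean_perm(#{random event positions with height ≥ h}) /
  #{observed sites with height ≥ h}`, clipped to [0, 1];
- FDR is monotonized by a running minimum over increasing height, so larger
  heights never get larger FDR and the `FDR < alpha` cut is well defined.
  `alpha = 1` keeps every site.

The randomization domain is the full genomic span, introns included — the
simplest null that preserves the gene's total signal; a caller can restrict
the domain by passing a different span. Redistributing events rather than
sites keeps the null's occupancy distribution faithful at high coverage.
Calibration on pure background (no planted signal, ~50 events/gene,
`n_perm=100`) yields a false-call fraction far below the nominal 0.05
(typically < 0.01): the estimator is conservative because the observed-site
count in the denominator counts distinct positions while the numerator
averages occupied random positions.

## Clusters, regions, CLIP scores

Peaks merge transitively while consecutive positions differ by strictly
less than `max_gap` (default 20 — at exactly 20 nt apart peaks do *not*
merge). The cluster interval is `[min_peak − flank, max_peak + flank + 1)`
with `flank = window = 3`: "adjacent signal" is not otherwise defined, and
tying adjacency to the FDR window is the least arbitrary choice (both are
configurable). The cluster score sums member peak scores and the scores of
non-peak sites inside the interval. A cluster's region is the label of its
midpoint with precedence 3'UTR > 5'UTR > CDS > intron, `other` outside all
features.

The CLIP score of a gene is the sum of its 3'UTR cluster scores. Profiles
are built for **every assayed gene** (zero score without 3'UTR clusters):
the dual percentile rule then operates on the full population, so with 1000
genes the top-10% cut keeps exactly 100. The retention rule keeps genes in
the top `ceil(clip_frac · N)` by CLIP score that are not in the top
`ceil(expr_frac · N)` by expression; both rank cutoffs use the full input
population with gene-id tie-breaks (deterministic), matching a plot with two
independent thresholds. Whether the CLIP cutoff should instead be computed
after removing expression outliers is genuinely ambiguous; a flag
(`threshold_after_exclusion`) provides that variant.

UGU occurrences are counted with overlaps (UGUGUGU → 3), case- and
T/U-insensitively. Per gene, only the 3'UTR-resolvable cluster with the
highest count is kept, and retained vs non-retained genes are compared at
the ≥ 3 UGU threshold with a 1-df Pearson chi-square (no continuity
correction by default, matching the large-sample use; correction is a flag).

## Ranking and GSEA-like enrichment

Genes are ranked by `sign(log2FC) · (−log10 FDR)` descending; FDR = 0 is
capped at half the smallest positive FDR (preserves rank order, avoids
infinities); ties break by |log2FC| descending then gene id, making the
order total. The enrichment score is the classic unweighted running sum:
+1/|S| per set member, −1/(N−|S|) per non-member, ES = signed maximal
deviation; the sum returns to zero at the end of the list. The unweighted
form was chosen because the signed-FDR statistic reliably carries rank
information only.

Significance uses gene-set resampling (same-size sets drawn without
replacement from the ranked universe) — the pipeline holds no sample-level
expression, so a phenotype-permutation null is unavailable. The one-sided
p-value is normalized against same-signed permutation scores with an
add-one correction:

    p = (1 + #{ES_perm ≥ ES_obs}) / (1 + #{ES_perm ≥ 0})   (ES_obs ≥ 0)

and mirrored for negative ES. Normalizing by all permutations instead
(`tail="global"`) halves the effective range of p and makes the null
p-value distribution Uniform(0, ~0.5); the signed normalization is what
makes repeated null runs of the whole procedure produce p ≈ Uniform(0, 1)
(verified by a KS test in the suite). For the permutation path the ES is
computed in closed form from sorted hit positions (the running profile
attains extrema only adjacent to hits); the closed form is cross-checked
against the explicit cumulative sum in the tests.

## Funnel

Six sequential filters with rank-based "upper quarter" cutoffs
(`k = ceil(0.25 · stage input)`, gene-id tie-break) computed within each
stage's survivors — the stages are drawn as sequential filtrations, so
stage-relative quartiles are the natural reading; a `global_quartiles` flag
computes them on the starting table instead. Note that in the original
study the citation-quartile stage retains fewer genes than a quarter of its
input would give, suggesting an additional unstated criterion; the package
implements the stated rule.

## Reporter statistics

Luciferase normalization is a fully multiplicative chain: per-well F/R →
median over technical replicates per (construct, condition, biological
replicate) → division by the control construct's median of the *same
condition and replicate* (within-replicate pairing maximizes cancellation of
batch effects; the legend's sequential wording does not pin this down) →
optional division by the control-effector value of the same construct and
replicate → log2. Consequently any per-replicate rescaling of firefly or
renilla cancels exactly (asserted in tests). Biological replicates are the
test units: two-sided one-sample t against 0 per construct,
Benjamini-Hochberg across the batch. Zero-variance constructs report p = 1
with a flag rather than failing, keeping batch processing total; n < 2 is
excluded with a warning.

Morphometry: area = minor × major diameter (an ellipse-area surrogate up to
the constant π/4, which cancels in ratios and paired differences);
lens/eye area ratio per larva side; two-sided paired t across larvae per
endpoint; unpaired larvae dropped with a warning.

## Synthetic-data generator

The generator emulates the study's structure, not its scale: two
pseudo-experiments on one synthetic chromosome of single-isoform genes
(5'UTR / CDS / optional intron / 3'UTR laid out contiguously, optional
minus-strand genes), with planted ground truth emitted separately and never
read by analysis code outside tests.

Defaults and why (chosen once, from the study design and a power sketch):

| parameter | default | rationale |
|---|---|---|
| `utr3_len_mean/sd` | 750 / 350 nt | typical mammalian 3'UTR scale |
| `base_composition` | uniform | background UGU rate ≈ 1/64 per position, keeping planted motifs distinctive |
| `site_motif` | `TGTTGTTGTTGT` | four tandem UGUs: planted clusters clear the ≥ 3 UGU threshold, background clusters rarely do |
| `sites_per_ligand` | 3 | a few discrete high-density regions per target |
| `signal_fraction` | 0.8 | strong planted binding against expression-correlated background |
| `expression_lognormal_mu/sigma` | 2.5 / 0.7 | TPM-like spread; sigma moderate so background cross-linking on highly expressed genes cannot out-score planted sites (a background gene would need ~30× the reads of a ligand, > 4 SD on the log scale) |
| `reads_per_gene_scale` | 8 | ~100 events for a median gene at depth 1 |
| `depth_factor_exp1/2` | 1.0 / 0.2 | the second experiment's harsher RNase digest yields ~5× fewer uniquely mapped reads |
| `de_lfc_mean/sd` | 1.0 / 0.5 | ligands upregulated ~2-fold in the knockout; p-values derive from the same normal draw, so null p is exactly uniform and BH behaves canonically |
| annotations | NB citations (ligand mean ×5), Bernoulli disease membership (0.35 vs 0.05), lens shift +1.5 SD | enough association for the funnel to discriminate without being degenerate |

Event counts are Poisson(expression × scale × depth) per gene; each event
falls into a planted site with probability `signal_fraction` (ligand genes),
else lands uniformly on the gene's genomic span, introns included — which is
what makes the cluster-region distribution non-trivial. Site scores per gene
sum exactly to the gene's event count. Everything derives from
`numpy.random.default_rng` seeded by the global seed combined with a CRC-32
hash of the stage name, so every output is reproducible independently of
stage execution order and identical config + seed gives byte-identical
files.

What the generator does **not** model: sequencing error, PCR duplicates /
UMIs, multi-isoform genes, mappability, cross-link-site sequence bias, and
overdispersion of expression beyond the log-normal. Passing tests therefore
demonstrate correctness of the statistics and the pipeline plumbing under a
clean generative model, not robustness to every artefact of real libraries.

## Problem sizes used in the checks

The self-contained checks run at desk scale: FDR calibration on 200
background genes (~10,000 sites), planted-ligand recovery on 1000 genes /
100 ligands with 100 permutations per gene, GSEA nulls with 199–1000
permutations, and a 100-gene end-to-end determinism run. These sizes give
stable pass/fail behaviour for the stated thresholds (recall/precision
≥ 0.8, false-call fraction ≤ 0.07, KS p > 0.01) while completing in minutes.

## Known limitations

- The permutation FDR is conservative (see above); it controls false calls
  well but its numerical value is not comparable across genes with very
  different site densities.
- Gene assignment of sites from alignments assumes non-overlapping genes.
- The funnel reproduces the stated filter sequence; stage order matters
  (quartiles are stage-relative) and permuting stages changes the result.
- The GSEA leading edge for negative ES follows the usual convention
  (members at or after the running-sum minimum) even though only the
  positive case is exercised by the study design.
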