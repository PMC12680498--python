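# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic cohort does and does not emulate, and
the design decisions taken where the procedure was genuinely open.

## Coordinates and record handling

VCF and GFF3 are 1-based inclusive on disk. All interval arithmetic
(containment, gaps, windows) happens on 0-based half-open intervals,
converted in one place (`interval0()` on the record types), and converted
back on write. Genotype tokens are kept as verbatim strings until
interpreted, because the focal-uniqueness rule is defined on token content
(`1|1` vs `2|2` vs `.|.`), and `|`/`/` separators are treated identically —
the rule concerns allele content, not phasing. Haploid tokens are rejected:
the panel is defined on haplotype samples, each carrying an `a|b` call.
Data lines round-trip byte-identically because records store the original
column strings.

## Focal-unique SV calling

The panel VCF comes from decomposing a pan-genome graph against the focal
genome, so REF is the focal sequence and each sample column is one
non-focal haplotype. A record is classified by its largest REF-vs-ALT
length difference d: d = 0 → SNP (1-bp REF) or MNP; 0 < d < 50 → indel;
d ≥ 50 → SV. A unique SV additionally requires that no genotype token
carries a `0` allele or a missing call and that every token is exactly
`1|1` (or `1/1`). Multi-allelic records are evaluated whole — no allele
splitting — so a panel fixed on a *second* alternate allele (`2|2`) is not
unique; splitting would change the semantics of the all-`1|1` rule. QUAL
and FILTER are ignored: uniqueness is a genotype-pattern property.

Direction is focal-centric and deliberately inverted relative to naive
VCF reading: REF longer than the query allele means the focal genome
carries sequence the rest of the panel lacks — an **insertion** from the
focal cultivar's perspective; REF shorter is a **deletion**. Equal lengths
have no presence/absence direction and raise an error.

## Hemizygous-gene calling

Deletion calls are retained iff `SVTYPE=DEL`, END present, precise
breakpoints, |SVLEN| ≥ 50 bp, QUAL ≥ 60 and read support ≥ 4 — every bound
inclusive, matching the printed `≥` signs. The precision flag reads
PRECISE when stated and defaults to precise only when IMPRECISE is also
absent; support comes from the first available of INFO `SUPPORT`, `RE`,
`DV` (caller-dialect drift). QUAL means the VCF QUAL column. A gene is
hemizygous when a retained deletion fully contains its body
(`gene_in_deletion`); a whole-gene hemizygote requires the gene inside the
deletion, although the literal alternative (`deletion_in_gene`) is
selectable. The filter is monotone in all three thresholds, and
containment is independent of call order.

## SV–gene linking and enrichment

"Within 5 kb" is the end-to-end gap between the two intervals — the number
of intervening bases, bedtools-`window` style — inclusive at exactly
5000 bp; overlapping pairs get distance 0. Book-ended intervals (zero
intervening bases without overlap) also get distance 0 but keep their
upstream/downstream relation, so "distance 0" does not strictly imply
overlap. Strand affects only the relation annotation, never eligibility.
Enrichment is the upper-tail hypergeometric test P(X ≥ k) per term from a
user-supplied flat gene→term table (no ontology propagation, no
downloads), Benjamini–Hochberg adjusted across tested terms.

## Single-nucleus stage

**QC.** Cells are kept with detected genes in [200, 7500] (inclusive; the
bounds read "between … and …") and UMIs strictly below 15 000 ("fewer
than"). Genes with zero total count over retained cells are dropped. The
filter is idempotent.

**Normalization.** value = ln(1 + count · 10⁴ / cell_total); zeros stay
zero, and the result depends only on within-cell proportions.

**Variable genes.** Per-sample vst-style standardized variance: a lowess
trend (span 0.3) of log₁₀ variance on log₁₀ mean predicts each gene's
expected sd; counts are standardized by it, clipped at √n_cells, and genes
are ranked by the variance of the standardized values. The two cultivars'
rankings are combined by best (minimum) rank — an integration-free
substitute for anchor-based feature selection that keeps genes highly
variable in either sample. Top 3000 genes by default.

**PCA and dimensionality.** Selected genes are centred and unit-scaled
within each sample before a joint PCA (deterministic full SVD) — the
package's substitute for anchor-based (CCA) integration; an externally
integrated embedding can be supplied instead. Variance fractions are
normalized over the retained components (the spectrum a Seurat-style
"proportion of variance per PC" analysis reads). The cutoff rule takes the
smallest j whose cumulative fraction exceeds 90% while the next component
explains < 5%; if no j qualifies, the smallest j where the drop between
consecutive fractions falls below 0.001 (the "variance drop stabilized"
signal; no printed value exists for this threshold, 0.001 is the
configurable default); otherwise all components. The clustering embedding
itself defaults to the study's working dimensionality of 13 components
(`n_dims = 13`, its printed `dimensions = 1:13`); setting `n_dims = None`
wires the cutoff rule's k through instead. The cutoff is computed and
reported in both cases. On synthetic data with an essentially flat noise
spectrum the cumulative-90% rule lands deep in the noise tail (≈ 0.9 ×
n_components) — a regime a real, strongly structured spectrum does not
produce — which is why the explicit working dimensionality is the default.

**Clustering.** Euclidean KNN (k = 20, including the cell itself),
Jaccard-weighted shared-neighbor edges pruned below 1/15, partitioned by
seeded Leiden modularity optimization (RB configuration) at resolution
0.4. Labels are renumbered by decreasing cluster size and are
deterministic under a fixed seed and invariant (up to relabeling) to cell
order.

**Wilcoxon rank-sum.** Exact two-sided p by enumerating the rank-sum null
(subset-sum dynamic programming) when the smaller group has ≤ 8
observations and no ties. Otherwise a normal approximation with
tie-corrected variance, continuity correction, and an Edgeworth kurtosis
term using the rank-sum null's excess kurtosis
γ₂ = −6(n² + m² + nm + n + m)/(5nm(N+1)); the plain corrected-normal tail
is off by up to 0.011 against enumeration at n = m = 8, the Edgeworth
refinement by ≤ 6·10⁻⁴.

**Markers and DEGs.** pct.1/pct.2 are the fractions of cells with count
> 0 in and out of the group; a gene is tested when the larger of the two
reaches min.pct (the cited toolkit's documented semantics). The effect
size is avg_log2FC = log₂((mean(expm1(in)) + 1)/(mean(expm1(out)) + 1)) on
normalized values (base-2 log of back-transformed means, pseudocount 1).
Markers are one-vs-rest, positive-only, min.pct 0.25, threshold 0.25;
DEGs compare the two cultivars within each cluster two-sidedly at
min.pct 0.1, threshold 0.25, with the direction recorded as
`up_in_<sample>`. Adjusted p is Bonferroni over the genes tested in that
comparison. Clusters with < 3 cells (markers) or missing one sample
(DEGs) are skipped with warnings. The consolidated DEG table keeps one row
per (gene, cluster); the deduplicated gene summary keeps each gene's
largest-|log2FC| row — both tallies are reported since a printed DEG count
may refer to either. Top-marker tables (n = 10/20/50) sort by descending
avg_log2FC with ties broken by ascending raw p, then gene id.

## Integration and co-expression

Candidates are the deduplicated intersection of SV-proximal gene ids with
DEG gene ids, annotated with both evidence tracks. TPM uses the annotated
gene span as the effective length (plain TPM from feature counts — no
fragment-length correction): rpk = count/(length/1000), TPM = 10⁶·rpk/Σrpk,
so each sample sums to 10⁶ exactly and per-sample scaling of counts cancels.
Zero-row filtering defaults to the stricter any-zero reading ("exclude rows
with zero values"), with an all-zero alternative. Spearman uses average
ranks for ties; constant profiles yield NaN with a warning, imputed as 0
(with a warning) for display ordering only. The display order is the leaf
order of average-linkage agglomeration on 1 − ρ, which is deterministic.

## Synthetic cohort: what it emulates, and what it does not

The generators reproduce the *structure* the pipeline's rules assume, at
desk scale, with every planted feature recorded in a truth object:

- **Panel VCF**: planted focal-unique SVs (all-`1|1`, Δ ≥ 50) among five
  decoy categories that each break exactly one clause — a `0`-carrying
  genotype, a partially genotyped panel, a missing call, a `2|2` panel on
  a multi-allelic record, and a sub-threshold (49 bp) length. SV REF spans
  are real reference substrings placed in intergenic space (5 bp margin)
  so linking truth stays unambiguous. Default SV length range 50–500 bp.
- **Deletion calls**: each truth gene fully inside a call passing every
  filter; each decoy violates exactly one criterion (QUAL 59, support 3,
  imprecise, 49 bp, END absent, partial overlap) and is anchored to its
  own non-truth gene. The 49-bp decoy cannot contain a whole gene, so it
  partially overlaps one; its single *filter* violation is still length.
- **Droplet counts**: gene base means log-normal(−0.5, 1); negative
  binomial with var = μ + 0.3μ² (gamma–Poisson); library sizes
  log-normal(0, 0.3). Cell types share the background program except
  `markers_per_type` genes elevated 2^2.0-fold in the owning type; each
  DEG gene sits on a moderately expressed background (mean 1–4, since
  detectable cultivar differences concern expressed transcripts) and is
  shifted 2^±0.5 between samples within one type, giving |log2FC| = 1.
  Planted QC failures break exactly one feasible bound (half-floor
  detected genes, or 1.3 × the UMI cap; a high-gene cell requires a gene
  universe above 7500, which desk-scale cohorts do not have). Ordinary
  cells are redrawn if a library-size outlier would cross a QC bound, so
  the planted failures are the only violations — a mild truncation that
  mirrors upstream barcode filtering in real data.
- **Bulk stages**: eight samples (five fruit stages F1–F5, inflorescence
  F6, leaf, buds). Planted pairs share a smooth latent profile (linear
  trend plus a Gaussian bump, values separated by ≥ 4 counts so integer
  rounding cannot create rank ties) times gene-specific scale and
  log-normal noise; remaining genes are independent across stages. With
  zero noise a planted pair has Spearman exactly 1 after TPM because TPM's
  per-sample divisor distorts both members identically.

Not emulated: genuine graph-decomposition artifacts (nested/overlapping
bubble records), read-level errors, doublets and ambient RNA, correlated
gene programs within a cell type, batch effects between replicates, and
real spectra's fast-decaying PC variance. Passing tests therefore
demonstrate that the *rules* are implemented exactly and are recoverable
under the stated noise model — not that the pipeline is robust to every
artifact of real sequencing data.

## Problem sizes and determinism

The test and acceptance runs use desk-scale cohorts chosen to keep the
statistical checks well-powered: 30-haplotype panels with 20 planted SVs
and 200 decoys (three replicates), 1000 deletions × 1000 genes for oracle
equivalence, 1000-gene droplet experiments with 200 cells per cultivar for
null calibration and 300 for planted-effect recovery (three replicates),
and full enumeration for the Wilcoxon (n = m ≤ 5 over values {0..9}) and
hypergeometric (N ≤ 30) oracles. Every stochastic step takes an explicit
seed; generators, PCA (full SVD), Leiden (seeded) and ordering steps are
deterministic, so identical config + seed reproduce byte-identical output
tables.

## Known limitations

- The anchor-based integration substitute (per-sample scaling + joint
  PCA) handles location/scale batch differences only; strong non-linear
  batch structure would need the external-embedding hook.
- Bonferroni over tested genes is conservative for discovery-style use;
  the DEG table retains raw p for alternative corrections.
- Hemizygosity is inferred purely from deletion-call geometry; no
  haplotype-resolved dosage evidence is used.
- The enrichment stage tests a flat term map; GO DAG propagation and term
  redundancy reduction are out of scope.
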