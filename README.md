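# vitiscfb

Integrative genomics of **continuous flowering and bearing (CFB)** in
grapevine. Most cultivars flower and fruit in one concentrated season
(seasonal flowering and bearing, SFB); a CFB vine carries inflorescences
and berries at mixed developmental stages simultaneously. This package
re-implements, as a tested and reusable pipeline, the integrative analysis
used to nominate CFB candidate genes in a focal cultivar:

1. **Focal-unique structural variants** (`vitiscfb.pangenome`) — from a
   multi-sample VCF produced by decomposing a pan-genome graph against the
   focal genome, call records private to the focal cultivar: allele-length
   delta ≥ 50 bp (the SV threshold) and every haplotype-sample genotype
   token exactly `1|1`. Direction is focal-centric: REF longer than the
   query allele ⇒ *insertion* (sequence the focal genome alone carries),
   REF shorter ⇒ *deletion*.
2. **Hemizygous genes** (`vitiscfb.hemizygosity`) — filter long-read
   deletion calls (`DEL`, END present, precise, length ≥ 50 bp, QUAL ≥ 60,
   support ≥ 4 reads) and report genes fully contained in a retained
   deletion.
3. **SV–gene linking and enrichment** (`vitiscfb.linking`) — genes within
   5 kb (end-to-end gap, inclusive) of a unique SV; term
   over-representation by the upper-tail hypergeometric test with
   Benjamini–Hochberg adjustment.
4. **Single-nucleus expression stage** (`vitiscfb.sc`) — QC (200 ≤ detected
   genes ≤ 7500, UMIs < 15 000), log-normalization
   ln(1 + 10⁴·count/total), top-3000 variable genes, gene-scaled PCA,
   shared-nearest-neighbor graph + seeded Leiden clustering at resolution
   0.4, one-vs-rest Wilcoxon cluster markers (only positive,
   min.pct 0.25, avg_log2FC ≥ 0.25), and per-cluster cross-cultivar DEGs
   (min.pct 0.1, |avg_log2FC| ≥ 0.25, Bonferroni).
5. **Integration and co-expression** (`vitiscfb.integrate`) — intersect
   SV-proximal genes with the DEG set to obtain candidates; TPM-normalize
   bulk stage counts (TPM_g = 10⁶ · rpk_g / Σrpk), drop zero-containing
   rows, and compute the pairwise Spearman matrix with average-linkage
   leaf ordering.

A synthetic-cohort generator (`vitiscfb.simulate`) produces every input
with known ground truth — planted focal-unique SVs among genotype-pattern
decoys, planted hemizygous deletions with single-criterion near-misses,
negative-binomial droplet counts with planted cell types / markers / DEGs /
QC failures, and stage-profiled bulk counts with planted co-expressed
pairs — so the whole pipeline is exercised without any downloads.

The single-cell steps are sklearn-style estimators (`QCFilter`,
`LogNormalizer`, `VariableGeneSelector`, `ScaledPCA`, `SNNLeiden`) that
compose with sklearn tooling; module functions wrap them for the
pipeline's genes × cells containers.

## Worked example

Simulate a cohort and run every stage (the `vitiscfb` console script):

```bash
vitiscfb all --seed 7 --out-dir demo
```

prints

```
synthetic cohort written to demo
20 unique SVs from 220 records
10 hemizygous genes (1.00% of 1000)
148 SV-gene links (147 genes)
2 clusters, 90 marker rows, 406 DEGs (deduplicated)
65 candidate genes
```

Reading the numbers: the panel VCF contains 220 records of which exactly
the 20 planted focal-private SVs survive the genotype filter; the ten
planted whole-gene deletions give ten hemizygous genes (1% of the
1000-gene catalog); 147 distinct genes lie within 5 kb of a unique SV;
the two planted cell types are recovered as 2 clusters with their marker
genes; and 65 genes carry both lines of evidence (SV-proximal **and**
differentially expressed between the cultivars). `demo/` holds the result
tables (`unique_svs.tsv`, `hemizygous_genes.tsv`, `sv_gene_links.tsv`,
`markers.csv`, `degs.csv`, `candidates.tsv`,
`candidate_correlations.tsv`), the generator's `truth.json`, and one JSON
manifest per stage recording the seed, parameters and output hashes —
identical config + seed reproduce byte-identical tables.

Library use mirrors the CLI:

```python
from vitiscfb.simulate import simulate_reference, simulate_pangenome_vcf
from vitiscfb.pangenome import find_unique_svs

ref = simulate_reference(seed=7)
records, truth = simulate_pangenome_vcf(ref, seed=7)
unique = find_unique_svs(records)           # exactly truth.planted_ids
```

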