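"""Synthetic-cohort generators with known ground truth for every stage.

Each generator emulates one input class of the study design — a focal
reference with gene models, a haplotype-panel VCF with planted
focal-specific SVs among genotype-pattern decoys, a long-read deletion-call
VCF with planted hemizygous genes and single-criterion near-miss decoys,
two-cultivar droplet count matrices with planted cell types / markers /
cross-cultivar DEGs / QC failures, and stage-profiled bulk counts with
planted co-expressed gene pairs.  All generators are deterministic under a
fixed seed, and their outputs pass the corresponding readers unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .records import CellMatrix, GeneModel, PanVariantRecord, SVCall
from . import io as vio

__all__ = [
    "Reference",
    "PanelTruth",
    "ScTruth",
    "BulkTruth",
    "simulate_reference",
    "simulate_pangenome_vcf",
    "simulate_sv_calls",
    "simulate_single_cell",
    "simulate_bulk_stages",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Reference + gene catalog
# ---------------------------------------------------------------------------

@dataclass
class Reference:
    sequences: dict[str, str]
    genes: list[GeneModel]

    def write(self, fasta_path, gff3_path) -> None:
        vio.write_fasta(fasta_path, self.sequences)
        vio.write_gff3(gff3_path, self.genes)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_reference(
    n_chroms: int = 2,
    chrom_len: int = 100_000,
    n_genes: int = 50,
    seed: int = 0,
    gene_len_range: tuple[int, int] = (300, 1500),
    out_dir=None,
) -> Reference:
    """Random reference sequences with uniformly placed non-overlapping genes.

    Gene ids are ``GeneNNN`` in genomic order.  With ``out_dir`` the FASTA
    and GFF3 are also written to disk.
    """
    rng = np.random.default_rng(seed)
    mean_len = sum(gene_len_range) / 2
    if n_genes * mean_len >= n_chroms * chrom_len:
        raise ValueError("gene catalog does not fit in the requested genome")
    sequences = {f"chr{i + 1}": _random_seq(rng, chrom_len) for i in range(n_chroms)}
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
                 for i in range(n_chroms)]
    genes: list[GeneModel] = []
    counter = 1
    for (chrom, _), k in zip(sequences.items(), per_chrom):
        if k == 0:
            continue
        lengths = rng.integers(gene_len_range[0], gene_len_range[1] + 1, size=k)
        free = chrom_len - int(lengths.sum()) - (k - 1)  # >=1 bp between genes
        if free < 0:
            raise ValueError(f"cannot pack {k} genes into {chrom}")
        cuts = np.sort(rng.integers(0, free + 1, size=k))
        start = 1
        prev_cut = 0
        for length, cut in zip(lengths, cuts):
            start += int(cut) - prev_cut
            prev_cut = int(cut)
            genes.append(
                GeneModel(
                    id=f"Gene{counter:03d}",
                    chrom=chrom,
                    start=start,
                    end=start + int(length) - 1,
                    strand=str(rng.choice(["+", "-"])),
                )
            )
            start += int(length) + 1
            counter += 1
    ref = Reference(sequences, genes)
    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ref.write(out_dir / "reference.fa", out_dir / "genes.gff3")
    return ref


# ---------------------------------------------------------------------------
# Haplotype-panel VCF with planted unique SVs
# ---------------------------------------------------------------------------

PANEL_DECOY_CATEGORIES = (
    "shared",
    "partially_genotyped",
    "missing_genotype",
    "non_1_1_allele",
    "sub_threshold",
)


@dataclass
class PanelTruth:
    """Ground truth for a simulated haplotype-panel VCF."""

    planted: list[tuple[str, str]]  # (record id, "insertion" | "deletion")
    decoys: dict[str, list[str]] = field(default_factory=dict)

    @property
    def planted_ids(self) -> set[str]:
        return {rid for rid, _ in self.planted}


class _Placer:
    """Collision-free placement of REF spans in intergenic space."""

    def __init__(self, reference: Reference, rng: np.random.Generator, margin: int = 5):
        self.rng = rng
        self.free: dict[str, list[tuple[int, int]]] = {}
        for chrom, seq in reference.sequences.items():
            occupied = sorted(
                (g.start - margin, g.end + margin)
                for g in reference.genes
                if g.chrom == chrom
            )
            free = []
            cursor = 1
            for s, e in occupied:
                if s - 1 >= cursor:
                    free.append((cursor, s - 1))
                cursor = max(cursor, e + 1)
            if cursor <= len(seq):
                free.append((cursor, len(seq)))
            self.free[chrom] = free

    def place(self, span: int) -> tuple[str, int]:
        """Reserve ``span`` reference bases; returns (chrom, 1-based pos)."""
        chroms = list(self.free)
        for _ in range(200):
            chrom = chroms[self.rng.integers(len(chroms))]
            slots = [iv for iv in self.free[chrom] if iv[1] - iv[0] + 1 >= span + 2]
            if not slots:
                continue
            s, e = slots[self.rng.integers(len(slots))]
            pos = int(self.rng.integers(s, e - span + 2))
            self.free[chrom].remove((s, e))
            if pos - 2 >= s:
                self.free[chrom].append((s, pos - 2))
            if pos + span <= e:
                self.free[chrom].append((pos + span, e))
            return chrom, pos
        raise ValueError("requested SVs exceed available placement space")


def _sv_alleles(
    rng: np.random.Generator,
    reference: Reference,
    placer: _Placer,
    delta: int,
    direction: str,
) -> tuple[str, int, str, str]:
    """REF/ALT pair with the requested focal-centric direction and delta."""
    if direction == "insertion":  # focal-specific sequence: REF longer
        chrom, pos = placer.place(delta + 1)
        ref = reference.sequences[chrom][pos - 1 : pos + delta]
        alt = ref[0]
    else:  # focal genome lacks sequence the panel carries: ALT longer
        chrom, pos = placer.place(1)
        ref = reference.sequences[chrom][pos - 1]
        alt = ref + _random_seq(rng, delta)
    return chrom, pos, ref, alt


def simulate_pangenome_vcf(
    reference: Reference,
    n_haplotype_samples: int = 30,
    n_planted_unique: int = 20,
    n_decoys_per_category: int = 40,
    sv_len_range: tuple[int, int] = (50, 500),
    seed: int = 0,
    sv_min_len: int = 50,
    planted_directions: Optional[Sequence[str]] = None,
    out_vcf=None,
) -> tuple[list[PanVariantRecord], PanelTruth]:
    """Panel VCF with planted focal-unique SVs among genotype-pattern decoys.

    Planted records have every genotype token ``1|1`` and an allele-length
    delta >= ``sv_min_len``; each decoy category breaks exactly one clause
    of the uniqueness rule (a 0-carrying genotype, a partially genotyped
    panel, a missing call, a non-1 alternate allele, or a sub-threshold
    length).  Records are position-sorted; sample columns are phased.
    """
    if n_haplotype_samples < 2:
        raise ValueError("a haplotype panel needs at least 2 samples")
    if planted_directions is not None and len(planted_directions) != n_planted_unique:
        raise ValueError("planted_directions length must equal n_planted_unique")
    rng = np.random.default_rng(seed)
    placer = _Placer(reference, rng)
    sample_names = [f"hap{i + 1:02d}" for i in range(n_haplotype_samples)]
    records: list[PanVariantRecord] = []
    truth = PanelTruth(planted=[], decoys={c: [] for c in PANEL_DECOY_CATEGORIES})

    def add_record(rid, chrom, pos, ref, alts, genotypes):
        records.append(
            PanVariantRecord(
                chrom=chrom, pos=pos, id=rid, ref=ref, alts=alts,
                qual_raw="60", filter_raw="PASS", info_raw=".",
                format="GT", samples=genotypes,
            )
        )

    def draw_delta() -> int:
        lo = max(sv_min_len, sv_len_range[0])
        return int(rng.integers(lo, sv_len_range[1] + 1))

    for i in range(n_planted_unique):
        rid = f"usv{i + 1:04d}"
        if planted_directions is not None:
            direction = planted_directions[i]
        else:
            direction = "insertion" if rng.random() < 0.5 else "deletion"
        chrom, pos, ref, alt = _sv_alleles(rng, reference, placer, draw_delta(), direction)
        add_record(rid, chrom, pos, ref, [alt], ["1|1"] * n_haplotype_samples)
        truth.planted.append((rid, direction))

    half = n_haplotype_samples // 2
    for cat in PANEL_DECOY_CATEGORIES:
        for i in range(n_decoys_per_category):
            rid = f"decoy_{cat}_{i + 1:04d}"
            direction = "insertion" if rng.random() < 0.5 else "deletion"
            delta = 49 if cat == "sub_threshold" else draw_delta()
            chrom, pos, ref, alt = _sv_alleles(rng, reference, placer, delta, direction)
            alts = [alt]
            if cat == "shared":
                gts = ["0|0"] * half + ["1|1"] * (n_haplotype_samples - half)
            elif cat == "partially_genotyped":
                gts = ["0|1"] * half + ["1|1"] * (n_haplotype_samples - half)
            elif cat == "missing_genotype":
                gts = ["1|1"] * n_haplotype_samples
                gts[int(rng.integers(n_haplotype_samples))] = ".|."
            elif cat == "non_1_1_allele":
                # multi-allelic record; every panel haplotype carries the
                # *second* ALT, so the raw tokens are 2|2, not 1|1
                snp_alt = ("T" if ref[0] != "T" else "G") + ref[1:]
                alts = [snp_alt, alt] if snp_alt != alt else [snp_alt, alt + "A"]
                gts = ["2|2"] * n_haplotype_samples
            else:  # sub_threshold
                gts = ["1|1"] * n_haplotype_samples
            add_record(rid, chrom, pos, ref, alts, gts)
            truth.decoys[cat].append(rid)

    order = {c: i for i, c in enumerate(reference.sequences)}
    records.sort(key=lambda r: (order[r.chrom], r.pos))
    if out_vcf is not None:
        vio.write_vcf(out_vcf, records, sample_names)
    return records, truth


# ---------------------------------------------------------------------------
# Long-read deletion calls with planted hemizygous genes
# ---------------------------------------------------------------------------

SV_CALL_DECOY_CATEGORIES = (
    "qual", "support", "imprecise", "length", "no_end", "partial_overlap",
)


def simulate_sv_calls(
    reference: Reference,
    genes: Optional[Sequence[GeneModel]] = None,
    n_hemi_genes: int = 10,
    n_near_miss_decoys: int = 6,
    seed: int = 0,
    out_vcf=None,
) -> tuple[list[SVCall], set[str]]:
    """Deletion-call VCF with planted hemizygous genes and near-miss decoys.

    Every truth gene is fully contained in a DEL call passing all filter
    thresholds (QUAL >= 60, support >= 4, precise, length >= 50, END
    present).  Each decoy violates exactly one criterion — QUAL 59,
    support 3, imprecise, length 49, END absent, or partial gene overlap —
    and is anchored to a distinct non-truth gene so that the violation is
    the only reason it drops out.
    """
    genes = list(reference.genes if genes is None else genes)
    if n_hemi_genes > len(genes):
        raise ValueError("more hemizygous genes requested than the catalog holds")
    if n_hemi_genes + n_near_miss_decoys > len(genes):
        raise ValueError("not enough genes to anchor decoys disjointly from truth")
    rng = np.random.default_rng(seed)
    chrom_len = {c: len(s) for c, s in reference.sequences.items()}
    picked = rng.choice(len(genes), size=n_hemi_genes + n_near_miss_decoys, replace=False)
    truth_genes = [genes[i] for i in picked[:n_hemi_genes]]
    decoy_genes = [genes[i] for i in picked[n_hemi_genes:]]

    records: list[PanVariantRecord] = []

    def add_del(rid, chrom, pos, end, qual, support, precise, with_end=True, svlen=None):
        if svlen is None:
            svlen = -(end - pos)
        info = [f"SVTYPE=DEL", f"SVLEN={svlen}"]
        if with_end:
            info.append(f"END={end}")
        info.append(f"SUPPORT={support}")
        info.append("PRECISE" if precise else "IMPRECISE")
        records.append(
            PanVariantRecord(
                chrom=chrom, pos=pos, id=rid, ref="N", alts=["<DEL>"],
                qual_raw=str(qual), filter_raw="PASS", info_raw=";".join(info),
                format="GT", samples=["0/1"],
            )
        )

    def spanning(g: GeneModel) -> tuple[int, int]:
        margin_l = int(rng.integers(10, 101))
        margin_r = int(rng.integers(10, 101))
        pos = max(1, g.start - margin_l)
        end = min(chrom_len[g.chrom], g.end + margin_r)
        return pos, end

    for i, g in enumerate(truth_genes):
        pos, end = spanning(g)
        add_del(
            f"hemi{i + 1:03d}", g.chrom, pos, end,
            qual=int(rng.integers(60, 100)), support=int(rng.integers(4, 21)),
            precise=True,
        )

    for i, g in enumerate(decoy_genes):
        cat = SV_CALL_DECOY_CATEGORIES[i % len(SV_CALL_DECOY_CATEGORIES)]
        rid = f"decoy_{cat}_{i + 1:03d}"
        pos, end = spanning(g)
        if cat == "qual":
            add_del(rid, g.chrom, pos, end, qual=59, support=8, precise=True)
        elif cat == "support":
            add_del(rid, g.chrom, pos, end, qual=80, support=3, precise=True)
        elif cat == "imprecise":
            add_del(rid, g.chrom, pos, end, qual=80, support=8, precise=False)
        elif cat == "length":
            short_end = g.start + 49
            add_del(rid, g.chrom, g.start, short_end, qual=80, support=8,
                    precise=True, svlen=-49)
        elif cat == "no_end":
            add_del(rid, g.chrom, pos, end, qual=80, support=8, precise=True,
                    with_end=False)
        else:  # partial_overlap: passes every filter, covers half the gene
            mid = (g.start + g.end) // 2
            add_del(rid, g.chrom, mid, end, qual=80, support=8, precise=True)

    order = {c: i for i, c in enumerate(reference.sequences)}
    records.sort(key=lambda r: (order[r.chrom], r.pos))
    if out_vcf is not None:
        vio.write_vcf(out_vcf, records, ["focal"])
    calls = [SVCall.from_record(r) for r in records]
    return calls, {g.id for g in truth_genes}


# ---------------------------------------------------------------------------
# Two-cultivar single-nucleus counts
# ---------------------------------------------------------------------------

@dataclass
class ScTruth:
    """Ground truth for the simulated two-cultivar droplet experiment."""

    cell_type_of_cell: dict[str, int]
    markers: dict[int, list[tuple[str, float]]]          # type -> (gene, log2FC)
    degs: dict[int, list[tuple[str, str, float]]]        # type -> (gene, direction, |log2FC|)
    low_quality_cells: list[tuple[str, str]]             # (barcode, violated bound)
    sample_names: tuple[str, str] = ("JA", "MH")

    @property
    def deg_genes(self) -> set[str]:
        return {g for rows in self.degs.values() for g, _, _ in rows}

    @property
    def marker_genes(self) -> set[str]:
        return {g for rows in self.markers.values() for g, _ in rows}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_single_cell(
    n_genes: int = 1000,
    cells_per_sample: int = 300,
    n_types: int = 2,
    markers_per_type: int = 20,
    n_degs: int = 60,
    effect_log2fc: float = 2.0,
    nb_dispersion: float = 0.3,
    n_bad_cells: int = 4,
    seed: int = 0,
    deg_log2fc: float = 1.0,
    sample_names: tuple[str, str] = ("JA", "MH"),
    min_genes: int = 200,
    max_genes: int = 7500,
    max_umi: int = 15000,
    gene_ids: Optional[Sequence[str]] = None,
) -> tuple[CellMatrix, CellMatrix, ScTruth]:
    """Negative-binomial droplet counts with planted structure.

    Cell types share a common expression program except for their
    ``markers_per_type`` marker genes (elevated ``effect_log2fc`` log2-fold
    in the owning type).  DEG genes are assigned to one type each and
    shifted ``deg_log2fc`` log2-fold between the two samples for cells of
    that type.  ``n_bad_cells`` planted QC failures each break exactly one
    feasible QC bound (low detected genes, or UMI total over ``max_umi``;
    a high-gene cell additionally requires ``n_genes > max_genes``).
    Library sizes vary log-normally.
    """
    if n_types < 2:
        raise ValueError("need at least 2 cell types")
    if effect_log2fc <= 0:
        raise ValueError("marker effect size must be positive")
    if n_degs > n_genes:
        raise ValueError("more DEGs requested than genes")
    if n_types * markers_per_type + n_degs > n_genes:
        raise ValueError("marker and DEG gene sets exceed the gene universe")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"Gene{i + 1:04d}" for i in range(n_genes)]
    else:
        gene_ids = list(gene_ids)
        if len(gene_ids) != n_genes:
            raise ValueError("gene_ids length must equal n_genes")
    base = rng.lognormal(mean=-0.5, sigma=1.0, size=n_genes)

    special = rng.choice(n_genes, size=n_types * markers_per_type + n_degs, replace=False)
    marker_idx = special[: n_types * markers_per_type].reshape(n_types, markers_per_type)
    deg_idx = special[n_types * markers_per_type:]
    # markers and DEGs sit on moderately expressed genes: cell-type programs
    # and cultivar differences are properties of expressed transcripts
    for t in range(n_types):
        base[marker_idx[t]] = rng.uniform(0.5, 2.0, size=markers_per_type)
    base[deg_idx] = rng.uniform(1.0, 4.0, size=len(deg_idx))
    deg_type = rng.integers(0, n_types, size=len(deg_idx))
    deg_up_first = rng.random(len(deg_idx)) < 0.5

    truth = ScTruth(
        cell_type_of_cell={},
        markers={
            t: [(gene_ids[g], effect_log2fc) for g in marker_idx[t]]
            for t in range(n_types)
        },
        degs={t: [] for t in range(n_types)},
        low_quality_cells=[],
        sample_names=sample_names,
    )
    for g, t, up in zip(deg_idx, deg_type, deg_up_first):
        direction = f"up_in_{sample_names[0] if up else sample_names[1]}"
        truth.degs[int(t)].append((gene_ids[g], direction, deg_log2fc))

    matrices = []
    for s_idx, sample in enumerate(sample_names):
        types = np.tile(np.arange(n_types), cells_per_sample // n_types + 1)[:cells_per_sample]
        rng.shuffle(types)
        cols = []
        barcodes = []
        for c in range(cells_per_sample):
            t = int(types[c])
            mu = base.copy()
            mu[marker_idx[t]] *= 2.0**effect_log2fc
            own = deg_type == t
            sign = np.where(deg_up_first == (s_idx == 0), 0.5, -0.5)
            mu[deg_idx[own]] *= 2.0 ** (deg_log2fc * sign[own])
            # redraw the rare library-size outlier that would cross a QC
            # bound: planted failures must be the only bound violations
            lo = min_genes if n_genes > 2 * min_genes else 0
            for _ in range(100):
                lib = rng.lognormal(0.0, 0.3)
                col = _nb_draw(rng, mu * lib, nb_dispersion)
                detected = int((col > 0).sum())
                if lo <= detected <= max_genes and col.sum() < max_umi:
                    break
            cols.append(col)
            bc = f"cell{c + 1:05d}-{sample}"
            barcodes.append(bc)
            truth.cell_type_of_cell[bc] = t
        # planted QC failures, alternating feasible violation categories
        bad_kinds = ["min_genes", "max_umi"]
        if n_genes > max_genes:
            bad_kinds.append("max_genes")
        n_bad = n_bad_cells // 2 + (n_bad_cells % 2 if s_idx == 0 else 0)
        for b in range(n_bad):
            kind = bad_kinds[b % len(bad_kinds)]
            col = np.zeros(n_genes, dtype=np.int64)
            if kind == "min_genes":
                n_detect = max(1, min_genes // 2)
                col[rng.choice(n_genes, size=n_detect, replace=False)] = 1
            elif kind == "max_umi":
                total = int(max_umi * 1.3)
                col = rng.multinomial(total, base / base.sum())
            else:  # max_genes: more distinct genes than the upper bound
                n_detect = min(n_genes, max_genes + max(1, max_genes // 10))
                col[rng.choice(n_genes, size=n_detect, replace=False)] = 1
            bc = f"badcell{b + 1:03d}-{sample}"
            cols.append(col)
            barcodes.append(bc)
            truth.low_quality_cells.append((bc, kind))
        counts = sp.csr_matrix(np.column_stack(cols))
        matrices.append(
            CellMatrix(counts, gene_ids, barcodes, [sample] * len(barcodes))
        )
    return matrices[0], matrices[1], truth


# ---------------------------------------------------------------------------
# Bulk stage counts with planted correlated pairs
# ---------------------------------------------------------------------------

@dataclass
class BulkTruth:
    """Ground truth for the simulated bulk stage series."""

    correlated_pairs: list[tuple[str, str]]
    gene_lengths: pd.Series
    stage_labels: list[str]


def _stage_labels(n_stages: int) -> list[str]:
    if n_stages == 8:
        # fruit stages F1-F5, inflorescence F6, leaf, buds
        return ["F1", "F2", "F3", "F4", "F5", "F6", "L", "B"]
    return [f"F{i + 1}" for i in range(n_stages)]


def _smooth_profile(rng: np.random.Generator, n_stages: int) -> np.ndarray:
    """Smooth positive stage profile with well-separated values.

    Separation keeps integer rounding from creating rank ties, so a
    noise-free planted pair has Spearman exactly 1 after TPM.
    """
    for _ in range(100):
        peak = rng.uniform(0, n_stages - 1)
        width = rng.uniform(1.0, 3.0)
        s = np.arange(n_stages)
        v = 200 + 120 * s + 3000 * np.exp(-((s - peak) ** 2) / (2 * width**2))
        if np.abs(np.subtract.outer(v, v))[~np.eye(n_stages, dtype=bool)].min() >= 4:
            return v
    raise RuntimeError("could not draw a well-separated stage profile")


def simulate_bulk_stages(
    genes: Sequence[GeneModel],
    n_stages: int = 8,
    n_corr_pairs: int = 5,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, BulkTruth]:
    """Bulk count table over developmental stages with planted co-expression.

    Each planted pair shares a smooth latent stage profile (times a
    gene-specific constant and log-normal noise of sd ``noise_sd``); all
    other genes are independent across stages.  Gene lengths are the
    annotated gene spans.
    """
    if n_stages < 4:
        raise ValueError("rank correlation needs at least 4 stages")
    genes = list(genes)
    if 2 * n_corr_pairs > len(genes):
        raise ValueError("not enough genes for the requested correlated pairs")
    rng = np.random.default_rng(seed)
    labels = _stage_labels(n_stages)
    gene_ids = [g.id for g in genes]
    lengths = pd.Series({g.id: g.length for g in genes}, name="length")

    counts = np.round(
        rng.lognormal(np.log(300.0), 1.0, size=(len(genes), n_stages))
    ).astype(np.int64)
    paired = rng.choice(len(genes), size=2 * n_corr_pairs, replace=False)
    pairs = []
    for i in range(n_corr_pairs):
        a, b = int(paired[2 * i]), int(paired[2 * i + 1])
        profile = _smooth_profile(rng, n_stages)
        for row in (a, b):
            scale = rng.uniform(0.5, 2.0)
            noise = (
                np.exp(rng.normal(0.0, noise_sd, size=n_stages))
                if noise_sd > 0
                else 1.0
            )
            counts[row] = np.round(scale * profile * noise).astype(np.int64)
        pairs.append((gene_ids[a], gene_ids[b]))
    table = pd.DataFrame(counts, index=gene_ids, columns=labels)
    return table, lengths, BulkTruth(pairs, lengths, labels)
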