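"""Core domain records shared across pipeline stages.

Coordinate convention: records mirror what is on disk (VCF and GFF3 are
1-based, inclusive).  All interval arithmetic (containment, gaps, windows)
is done on 0-based half-open intervals; :meth:`GeneModel.interval0` and
:meth:`SVCall.interval0` perform the conversion in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "PanVariantRecord",
    "SVCall",
    "GeneModel",
    "CellMatrix",
]



@dataclass
class PanVariantRecord:
    """One row of a multi-sample pan-genome VCF.

    Genotype tokens are kept verbatim (e.g. ``"1|1"``, ``"0/1"``, ``".|."``):
    the focal-cultivar uniqueness rule is defined on raw token content, and
    byte-level round-tripping requires the original strings.  ``qual_raw``,
    ``filter_raw`` and ``info_raw`` likewise preserve the on-disk text.
    """

    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alts: list[str]
    qual_raw: str = "."
    filter_raw: str = "."
    info_raw: str = "."
    format: Optional[str] = None
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if not self.ref or not self.alts or any(not a for a in self.alts):
            raise ValueError(f"record {self.id!r}: REF and ALT alleles must be non-empty")

    # -- typed views -------------------------------------------------------

    @property
    def qual(self) -> Optional[float]:
        return None if self.qual_raw in (".", "") else float(self.qual_raw)

    @property
    def info(self) -> dict[str, Optional[str]]:
        """INFO parsed into a dict; flag keys map to ``None``."""
        out: dict[str, Optional[str]] = {}
        if self.info_raw in (".", ""):
            return out
        for item in self.info_raw.split(";"):
            if not item:
                continue
            if "=" in item:
                k, v = item.split("=", 1)
                out[k] = v
            else:
                out[item] = None
        return out

    @property
    def genotypes(self) -> list[str]:
        """Verbatim GT token per haplotype sample (first FORMAT field)."""
        if self.format is None:
            return []
        fields = self.format.split(":")
        try:
            gt_idx = fields.index("GT")
        except ValueError:
            raise ValueError(f"record {self.id!r}: FORMAT has no GT field")
        return [s.split(":")[gt_idx] for s in self.samples]

    def genotype_alleles(self) -> list[list[str]]:
        """Split each GT token on ``|`` or ``/`` (phasing is irrelevant here).

        Haploid tokens are rejected: the panel is defined on haplotype
        samples, each carrying a diploid-style a|b call.
        """
        out = []
        for tok in self.genotypes:
            alleles = tok.replace("/", "|").split("|")
            if len(alleles) < 2:
                raise ValueError(
                    f"record {self.id!r}: haploid genotype token {tok!r}; "
                    "the haplotype panel requires a|b (or a/b) calls"
                )
            out.append(alleles)
        return out

    def to_line(self) -> str:
        cols = [
            self.chrom,
            str(self.pos),
            self.id,
            self.ref,
            ",".join(self.alts),
            self.qual_raw,
            self.filter_raw,
            self.info_raw,
        ]
        if self.format is not None:
            cols.append(self.format)
            cols.extend(self.samples)
        return "\t".join(cols)


@dataclass
class SVCall:
    """One long-read SV-caller record (Sniffles-style dialect).

    ``end`` comes from INFO END and may be absent; ``svlen`` is stored as an
    absolute length; ``precise`` follows the PRECISE/IMPRECISE flags with
    "precise unless stated imprecise" as the fallback; read support is read
    from the first of INFO SUPPORT, RE, DV.
    """

    chrom: str
    pos: int  # 1-based
    id: str
    svtype: str
    svlen: Optional[int]
    end: Optional[int]
    qual: Optional[float]
    support: int
    precise: bool

    def __post_init__(self) -> None:
        if self.end is not None and self.end < self.pos:
            raise ValueError(f"SV call {self.id!r}: END {self.end} < POS {self.pos}")
        if self.support < 0:
            raise ValueError(f"SV call {self.id!r}: negative read support")

    @classmethod
    def from_record(cls, rec: PanVariantRecord) -> "SVCall":
        info = rec.info
        if "SVTYPE" not in info or info["SVTYPE"] is None:
            raise ValueError(f"record {rec.id!r}: missing INFO SVTYPE")
        end = int(info["END"]) if info.get("END") is not None else None
        svlen = None
        if info.get("SVLEN") is not None:
            svlen = abs(int(float(info["SVLEN"])))
        precise = ("PRECISE" in info) or ("IMPRECISE" not in info)
        support = 0
        for key in ("SUPPORT", "RE", "DV"):
            if info.get(key) is not None:
                support = int(info[key])
                break
        return cls(
            chrom=rec.chrom,
            pos=rec.pos,
            id=rec.id,
            svtype=str(info["SVTYPE"]),
            svlen=svlen,
            end=end,
            qual=rec.qual,
            support=support,
            precise=precise,
        )

    def interval0(self) -> tuple[int, int]:
        """0-based half-open span; END-less calls fall back to POS+|SVLEN|."""
        end = self.end if self.end is not None else self.pos + (self.svlen or 1) - 1
        return self.pos - 1, end


@dataclass(frozen=True)
class GeneModel:
    """A gene interval from GFF3 (1-based inclusive)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id!r}: start {self.start} > end {self.end}")

    def interval0(self) -> tuple[int, int]:
        return self.start - 1, self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class CellMatrix:
    """Sparse gene x cell count matrix with a sample-of-origin label per cell.

    This is the droplet-data container consumed by the single-nucleus stage:
    rows are genes, columns are cell (nucleus) barcodes, entries are UMI
    counts.  ``to_anndata`` bridges to the scanpy/anndata ecosystem.
    """

    def __init__(
        self,
        counts: sp.spmatrix,
        gene_ids: Sequence[str],
        barcodes: Sequence[str],
        sample_of_cell: Sequence[str],
    ) -> None:
        counts = sp.csr_matrix(counts)
        if counts.shape != (len(gene_ids), len(barcodes)):
            raise ValueError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(gene_ids)} genes x {len(barcodes)} barcodes"
            )
        if len(sample_of_cell) != len(barcodes):
            raise ValueError("one sample label per barcode required")
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if counts.nnz and np.any(counts.data != np.round(counts.data)):
            raise ValueError("counts must be integers")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate cell barcodes")
        self.counts = counts
        self.gene_ids = list(gene_ids)
        self.barcodes = list(barcodes)
        self.sample_of_cell = np.asarray(sample_of_cell, dtype=object)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def genes_per_cell(self) -> np.ndarray:
        """Detected genes (count > 0) per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def umis_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset(self, gene_mask=None, cell_mask=None) -> "CellMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        return CellMatrix(
            self.counts[gm][:, cm],
            [g for g, k in zip(self.gene_ids, gm) if k],
            [b for b, k in zip(self.barcodes, cm) if k],
            self.sample_of_cell[cm],
        )

    def concat(self, other: "CellMatrix") -> "CellMatrix":
        if self.gene_ids != other.gene_ids:
            raise ValueError("cell matrices must share the gene namespace")
        return CellMatrix(
            sp.hstack([self.counts, other.counts]).tocsr(),
            self.gene_ids,
            self.barcodes + other.barcodes,
            np.concatenate([self.sample_of_cell, other.sample_of_cell]),
        )

    def to_anndata(self):
        """Cells x genes AnnData view (requires anndata)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=pd.DataFrame({"sample": self.sample_of_cell}, index=self.barcodes),
            var=pd.DataFrame(index=self.gene_ids),
        )
        return adata

    def __repr__(self) -> str:  # pragma: no cover
        return f"CellMatrix({self.n_genes} genes x {self.n_cells} cells, nnz={self.counts.nnz})"
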