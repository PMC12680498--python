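"""Pipeline configuration with the published defaults for every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable thresholds, initialised to the study's printed values.

    Units: lengths/windows in bp; ``max_umi`` in UMI counts; variance
    thresholds are fractions of total variance.
    """

    seed: int = 0

    # pan-genome unique-SV stage
    sv_min_len: int = 50           # bp; minimum allele-length delta for an SV

    # hemizygosity stage (long-read deletion-call filter)
    hemi_min_len: int = 50         # bp
    hemi_min_qual: float = 60.0
    hemi_min_support: int = 4      # reads
    hemi_mode: str = "gene_in_deletion"

    # SV-gene linking
    window: int = 5000             # bp, inclusive at exactly 5 kb
    alpha: float = 0.05            # enrichment significance level (BH-adjusted)

    # single-nucleus stage
    qc_min_genes: int = 200
    qc_max_genes: int = 7500
    qc_max_umi: int = 15000        # strict upper bound ("fewer than")
    norm_scale: float = 10000.0
    n_variable_genes: int = 3000
    n_pcs: int = 50
    # embedding dimensionality for neighbors/clustering; the study ran
    # FindNeighbors on dimensions 1:13.  None derives it from the
    # variance-spectrum cutoff rule instead.
    n_dims: Optional[int] = 13
    cum_var_threshold: float = 0.90
    indiv_var_threshold: float = 0.05
    delta_var_threshold: float = 0.001
    k_neighbors: int = 20
    resolution: float = 0.4
    marker_min_pct: float = 0.25
    marker_logfc: float = 0.25
    deg_min_pct: float = 0.1
    deg_logfc: float = 0.25

    # co-expression
    zero_row_policy: str = "any_zero"

    # paths (filled in by the CLI)
    input_dir: Optional[str] = None
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        positive = [
            "sv_min_len", "hemi_min_len", "hemi_min_qual", "hemi_min_support",
            "window", "alpha", "qc_min_genes", "qc_max_genes", "qc_max_umi",
            "norm_scale", "n_variable_genes", "n_pcs", "cum_var_threshold",
            "indiv_var_threshold", "delta_var_threshold", "k_neighbors",
            "resolution", "marker_min_pct", "marker_logfc", "deg_min_pct",
            "deg_logfc",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config threshold {name} must be strictly positive")
        if self.qc_min_genes > self.qc_max_genes:
            raise ValueError("qc_min_genes > qc_max_genes")
        if self.hemi_mode not in ("gene_in_deletion", "deletion_in_gene"):
            raise ValueError(f"unknown hemi_mode {self.hemi_mode!r}")
        if self.zero_row_policy not in ("any_zero", "all_zero"):
            raise ValueError(f"unknown zero_row_policy {self.zero_row_policy!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load a YAML (or JSON — valid YAML) key/value config file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
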