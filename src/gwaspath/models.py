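"""Core data model for the GWAS → pathway scoring pipeline.

The pipeline moves through four representations: per-marker association
records, linkage groups collapsed to tagSNPs, per-gene effect assignments,
and per-pathway enrichment results.  Everything here is a plain dataclass;
bulk numerics stay in numpy/pandas inside the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class MarkerRecord:
    """One biallelic SNP with its trait-association statistics.

    ``effect`` is the single signed allelic effect retained after collapsing
    the two allele rows (see :func:`gwaspath.io.merge_and_filter`);
    ``marker_r2`` is the coefficient of determination of the SNP/trait
    association.
    """

    marker_id: str
    chromosome: str
    position: int
    trait: str
    p_value: float
    marker_r2: float
    effect: float
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if len(self.alleles) != 2:
            raise ValueError("exactly two alleles per marker")
        if np.isnan(self.marker_r2):
            raise ValueError("marker_r2 must be non-missing")


@dataclass(frozen=True)
class LDPair:
    """One intra-chromosome pairwise LD record (r² between two sites)."""

    locus: str
    position_a: int
    position_b: int
    site_a: int
    site_b: int
    dist_bp: int
    ld_r2: float

    def __post_init__(self) -> None:
        if self.dist_bp != abs(self.position_b - self.position_a):
            raise ValueError("dist_bp must equal |position_b - position_a|")
        if np.isnan(self.ld_r2):
            raise ValueError("ld_r2 must be non-missing")


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval from the annotation (1-based, inclusive)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass(frozen=True)
class PathwayDef:
    """A named pathway and the set of genes annotated to it."""

    pathway_id: str
    pathway_name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"pathway {self.pathway_id} has no genes")


class GroupKind(str, Enum):
    UNLINKED = "unlinked"
    PAIR = "pair"
    BLOCK = "block"


#: Sentinel returned by pair tagSNP election when the two SNPs have opposite
#: effect signs and identical p-values; such pairs are dropped.
PROBLEMATIC = "PROBLEMATIC"


@dataclass
class LinkageGroup:
    """A set of SNPs classified unlinked / pair / block with its tagSNP.

    ``members`` are marker ids ordered by genomic position.  ``common_snp``
    is set for blocks only (the highest-degree member).  ``tag_snp`` is absent
    only for problematic pairs.
    """

    kind: GroupKind
    members: list[str]
    common_snp: Optional[str] = None
    tag_snp: Optional[str] = None
    n_linked: int = 0

    def __post_init__(self) -> None:
        if self.kind is GroupKind.UNLINKED and len(self.members) != 1:
            raise ValueError("unlinked group must have exactly one member")
        if self.kind is GroupKind.PAIR and len(self.members) != 2:
            raise ValueError("pair group must have exactly two members")
        if self.kind is GroupKind.BLOCK:
            if len(self.members) < 3:
                raise ValueError("block group must have >= 3 members")
            if self.common_snp not in self.members:
                raise ValueError("block common_snp must be a member")


@dataclass
class GeneAssignment:
    """A gene carrying the effect/p inherited from its tagSNP(s).

    ``contributing_tags`` holds ``(marker_id, effect, p, n_linked)`` for every
    tagSNP within the window; ``(effect, p_value)`` equals one of those pairs
    and ``n_linked_snps`` is the sum of their ``n_linked``.
    """

    gene_id: str
    chromosome: str
    effect: float
    p_value: float
    n_linked_snps: int
    contributing_tags: list[tuple[str, float, float, int]] = field(default_factory=list)


@dataclass
class RunningSum:
    """Per-rank cumulative enrichment trace for one pathway."""

    values: np.ndarray            # S_1..S_N
    peak_rank: int                # 1-based arg max
    es: float                     # max_i S_i

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class PathwayResult:
    """Scored pathway: observed ES, null moments, z, p, q, and the trace."""

    pathway_id: str
    pathway_name: str
    n_genes: int                  # pathway genes present in the ranking
    es_observed: float
    null_mean: float
    null_sd: float
    z: float
    p_value: float
    q_value: float = float("nan")
    running_sum: Optional[RunningSum] = None
    hit_ranks: Optional[list[int]] = None   # 1-based ranks of pathway genes
    degenerate_null: bool = False
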