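"""How linkage groups collapse to a single tagSNP.

Builds a small LD table by hand — one pair, one three-SNP block, one
problematic pair — and shows which SNP each group elects, including the
tie-break branches.
"""

from gwaspath import build_linkage_graph, collapse_to_tagsnps, partition_groups
from gwaspath.models import LDPair, MarkerRecord


def snp(mid, pos, effect, p):
    return MarkerRecord(
        marker_id=mid, chromosome="chr1", position=pos, trait="t",
        p_value=p, marker_r2=0.2, effect=effect, alleles=("A", "G"),
    )


def ld(pa, pb, r2):
    return LDPair(locus="chr1", position_a=pa, position_b=pb, site_a=0,
                  site_b=1, dist_bp=pb - pa, ld_r2=r2)


markers = [
    snp("pair_a", 1_000, +2.0, 0.05), snp("pair_b", 1_200, +3.0, 0.10),
    snp("blk_a", 5_000, -3.0, 0.02), snp("blk_b", 5_100, -1.0, 0.04),
    snp("blk_c", 5_200, +2.0, 0.03),
    snp("bad_a", 9_000, +2.0, 0.05), snp("bad_b", 9_300, -3.0, 0.05),
    snp("alone", 20_000, +0.5, 0.50),
]
pairs = [
    ld(1_000, 1_200, 0.95),                 # pair: same sign, |3| > |2|
    ld(5_000, 5_100, 0.9), ld(5_000, 5_200, 0.9),  # star block around blk_a
    ld(9_000, 9_300, 0.99),                 # opposite signs, equal p
]

groups = partition_groups(build_linkage_graph(pairs, r2_cutoff=0.8), markers)
tags, n_problematic = collapse_to_tagsnps(groups, markers)

for g in groups:
    print(f"{g.kind.value:9s} members={g.members} -> tagSNP={g.tag_snp}")
print(f"\nproblematic pairs dropped: {n_problematic}")
print("the pair takes the larger |effect|; the block is majority-negative so")
print("the most negative SNP wins; opposite signs with equal p elect nobody.")
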