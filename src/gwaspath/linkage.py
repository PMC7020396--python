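"""Partition SNPs into linkage groups and elect one tagSNP per group.

Two SNPs are linked when their pairwise LD r² strictly exceeds the cutoff.
Connected components of the resulting graph are classified as unlinked
(size 1), singly-linked pairs (size 2) or blocks (size ≥ 3).  Each group is
collapsed to a single tagSNP by deterministic tie-break rules so that one
effect, p-value and R² can be transferred downstream:

* unlinked SNP — the SNP is its own tagSNP;
* pair, same effect sign — larger \\|effect| wins; equal effects — the
  downstream (second) SNP wins;
* pair, opposite signs — lower p wins; equal p — no tagSNP can be elected
  and the pair is dropped as *problematic*;
* block — majority effect sign wins and the extreme effect of that sign is
  the tagSNP; a sign-count tie is broken by the sign of the block's common
  SNP (the member linked to most others).

Zero effects count as neither positive nor negative in the sign tallies.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Union

import networkx as nx

from .models import PROBLEMATIC, GroupKind, LDPair, LinkageGroup, MarkerRecord

logger = logging.getLogger("gwaspath")

Node = tuple[str, int]  # (locus/chromosome, position)


def build_linkage_graph(
    ld: Union[dict[str, list[LDPair]], Iterable[LDPair]],
    r2_cutoff: float,
) -> nx.Graph:
    """Build the linkage graph over (locus, position) nodes.

    An undirected edge joins two sites iff their LD r² strictly exceeds
    ``r2_cutoff`` ("exceed" is implemented as ``>``, never ``>=``).  Every
    site that appears in the LD table becomes a node, so sites whose only
    pairs fall at or below the cutoff end up as isolated vertices.
    """
    if not 0.0 <= r2_cutoff <= 1.0:
        raise ValueError(f"r2_cutoff must be in [0, 1], got {r2_cutoff}")
    if isinstance(ld, dict):
        pairs: Iterable[LDPair] = (p for group in ld.values() for p in group)
    else:
        pairs = ld
    graph: nx.Graph = nx.Graph()
    for pair in pairs:
        a: Node = (pair.locus, pair.position_a)
        b: Node = (pair.locus, pair.position_b)
        graph.add_node(a)
        graph.add_node(b)
        if pair.ld_r2 > r2_cutoff:
            graph.add_edge(a, b)
    return graph


def partition_groups(
    graph: nx.Graph, markers: list[MarkerRecord]
) -> list[LinkageGroup]:
    """Classify every marker into exactly one unlinked/pair/block group.

    Markers absent from the graph (no LD data at all) are unlinked.  Graph
    nodes with no matching marker are ignored with a warning — they are LD
    sites that were filtered out of the association data upstream.  Block
    ``common_snp`` is the member with highest degree (ties broken by smallest
    position); members are position-sorted.
    """
    by_node: dict[Node, MarkerRecord] = {
        (m.chromosome, m.position): m for m in markers
    }
    orphan_nodes = [n for n in graph.nodes if n not in by_node]
    if orphan_nodes:
        logger.warning(
            "linkage: %d LD site(s) have no matching marker and are ignored",
            len(orphan_nodes),
        )
    sub = graph.subgraph(n for n in graph.nodes if n in by_node)
    groups: list[LinkageGroup] = []
    covered: set[Node] = set()
    for component in nx.connected_components(sub):
        nodes = sorted(component, key=lambda n: n[1])
        covered.update(nodes)
        members = [by_node[n].marker_id for n in nodes]
        if len(nodes) == 1:
            groups.append(
                LinkageGroup(
                    kind=GroupKind.UNLINKED,
                    members=members,
                    tag_snp=members[0],
                    n_linked=1,
                )
            )
        elif len(nodes) == 2:
            groups.append(LinkageGroup(kind=GroupKind.PAIR, members=members, n_linked=2))
        else:
            common_node = min(nodes, key=lambda n: (-sub.degree(n), n[1]))
            groups.append(
                LinkageGroup(
                    kind=GroupKind.BLOCK,
                    members=members,
                    common_snp=by_node[common_node].marker_id,
                    n_linked=len(members),
                )
            )
    # markers never seen in the LD table are unlinked singletons
    for marker in markers:
        node = (marker.chromosome, marker.position)
        if node not in covered:
            groups.append(
                LinkageGroup(
                    kind=GroupKind.UNLINKED,
                    members=[marker.marker_id],
                    tag_snp=marker.marker_id,
                    n_linked=1,
                )
            )
    return groups


def select_tag_pair(a: MarkerRecord, b: MarkerRecord) -> str:
    """Elect the tagSNP of a singly-linked pair (``a`` upstream of ``b``).

    Returns the winning marker id, or :data:`~gwaspath.models.PROBLEMATIC`
    when the effects have opposite signs and the p-values are identical.
    """
    if a.position >= b.position:
        raise ValueError("pair must be ordered by position (a upstream of b)")
    if a.effect * b.effect < 0:  # opposite signs: lowest p decides
        if a.p_value < b.p_value:
            return a.marker_id
        if b.p_value < a.p_value:
            return b.marker_id
        return PROBLEMATIC
    if abs(a.effect) > abs(b.effect):
        return a.marker_id
    # larger |effect| wins; equal effects fall to the downstream SNP
    return b.marker_id


def select_tag_block(members: list[MarkerRecord], common: str) -> str:
    """Elect the tagSNP of a block (≥ 3 members) around its common SNP.

    Majority sign wins: more positive effects → largest positive effect;
    more negative → most negative effect.  A sign-count tie takes the sign
    of the common SNP's own effect; if that effect is zero the fallback is
    the largest \\|effect| overall.  Remaining ties go to the smallest
    position.
    """
    if len(members) < 3:
        raise ValueError("block must have >= 3 members")
    common_rec = next((m for m in members if m.marker_id == common), None)
    if common_rec is None:
        raise ValueError(f"common SNP {common!r} is not a block member")
    positives = [m for m in members if m.effect > 0]
    negatives = [m for m in members if m.effect < 0]

    def _largest_positive() -> MarkerRecord:
        return min(positives, key=lambda m: (-m.effect, m.position))

    def _most_negative() -> MarkerRecord:
        return min(negatives, key=lambda m: (m.effect, m.position))

    def _largest_abs() -> MarkerRecord:
        return min(members, key=lambda m: (-abs(m.effect), m.position))

    if len(positives) > len(negatives):
        return _largest_positive().marker_id
    if len(negatives) > len(positives):
        return _most_negative().marker_id
    # tie: follow the sign of the common SNP
    if common_rec.effect > 0 and positives:
        return _largest_positive().marker_id
    if common_rec.effect < 0 and negatives:
        return _most_negative().marker_id
    return _largest_abs().marker_id


def collapse_to_tagsnps(
    groups: list[LinkageGroup], markers: list[MarkerRecord]
) -> tuple[list[tuple[MarkerRecord, int]], int]:
    """Reduce every group to its tagSNP record.

    Returns ``(tags, n_problematic)`` where ``tags`` holds one
    ``(MarkerRecord, n_linked)`` per non-problematic group — the tagSNP keeps
    its own effect, p and R² — and ``n_problematic`` counts dropped pairs.
    Each group's ``tag_snp`` field is filled in as a side effect.
    """
    by_id = {m.marker_id: m for m in markers}
    tags: list[tuple[MarkerRecord, int]] = []
    n_problematic = 0
    for group in groups:
        if group.kind is GroupKind.UNLINKED:
            tag: Optional[str] = group.members[0]
        elif group.kind is GroupKind.PAIR:
            a, b = (by_id[mid] for mid in group.members)
            result = select_tag_pair(a, b)
            tag = None if result == PROBLEMATIC else result
        else:
            tag = select_tag_block(
                [by_id[mid] for mid in group.members], group.common_snp
            )
        group.tag_snp = tag
        if tag is None:
            n_problematic += 1
            continue
        tags.append((by_id[tag], group.n_linked))
    if n_problematic:
        logger.info(
            "linkage: %d problematic pair(s) dropped (opposite signs, equal p)",
            n_problematic,
        )
    return tags, n_problematic
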