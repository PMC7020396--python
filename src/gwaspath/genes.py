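"""Transfer tagSNP effects and p-values to genes within a physical window.

A tagSNP is assigned to every gene on its chromosome whose distance is at
most ``window`` bp, where the distance is zero if the SNP falls inside the
gene and otherwise the gap to the nearest gene boundary; strand is ignored.
When several tagSNPs (blocks or unlinked SNPs) hit the same gene, one
(effect, p) pair is chosen by majority effect sign, and the gene's linked-SNP
count is the sum of the groups' sizes.
"""

from __future__ import annotations

import logging

from intervaltree import IntervalTree

from .models import GeneAssignment, GeneFeature, MarkerRecord

logger = logging.getLogger("gwaspath")

#: (effect, p, n_linked) optionally followed by the tag's position — the
#: position participates only in the final tie-break.
Candidate = tuple


class GeneIndex:
    """Per-chromosome interval index over gene bodies."""

    def __init__(self, genes: list[GeneFeature]):
        self.genes = {g.gene_id: g for g in genes}
        if len(self.genes) != len(genes):
            raise ValueError("gene_id must be unique within the annotation")
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.chromosome, IntervalTree())
            # half-open interval over the 1-based inclusive gene body
            tree.addi(g.start, g.end + 1, g.gene_id)

    def query(self, chromosome: str, position: int, window: int) -> list[str]:
        """Gene ids within ``window`` bp of ``position`` (0 = containment)."""
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        hits = tree.overlap(position - window, position + window + 1)
        return sorted(iv.data for iv in hits)


def find_genes_near_tagsnp(
    tag: MarkerRecord, genes: "GeneIndex | list[GeneFeature]", window: int
) -> list[str]:
    """Every gene on the tag's chromosome within ``window`` bp of it."""
    if window < 0:
        raise ValueError("window must be >= 0")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return index.query(tag.chromosome, tag.position, window)


def resolve_gene_effect(candidates: list[Candidate]) -> tuple[float, float, int]:
    """Pick the (effect, p) a gene inherits from its candidate tagSNPs.

    One candidate is taken verbatim.  Otherwise positive and negative effects
    are tallied (zeros count as neither): a negative majority takes the most
    negative effect, a positive majority the largest positive effect; equal
    extreme effects within the winning sign fall to the lowest p; an equal
    sign count takes the greatest \\|effect|, with residual ties broken by
    lower p, then the positive effect, then smaller marker position.
    Returns ``(effect, p, total_n_linked)``.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    total = sum(int(c[2]) for c in candidates)
    if len(candidates) == 1:
        eff, p = float(candidates[0][0]), float(candidates[0][1])
        return eff, p, total

    def _pos(c: Candidate) -> float:
        return float(c[3]) if len(c) > 3 else 0.0

    positives = [c for c in candidates if c[0] > 0]
    negatives = [c for c in candidates if c[0] < 0]
    if len(negatives) > len(positives):
        best = min(negatives, key=lambda c: (c[0], c[1], _pos(c)))
    elif len(positives) > len(negatives):
        best = min(positives, key=lambda c: (-c[0], c[1], _pos(c)))
    else:
        # equal sign counts: greatest |effect|; ties → lower p → positive → position
        best = min(candidates, key=lambda c: (-abs(c[0]), c[1], -c[0], _pos(c)))
    return float(best[0]), float(best[1]), total


def assign_all_genes(
    tags: list[tuple[MarkerRecord, int]],
    genes: "GeneIndex | list[GeneFeature]",
    window: int,
) -> list[GeneAssignment]:
    """Map every tagSNP to nearby genes and resolve multi-tag collisions.

    Genes with no tagSNP within the window are absent from the output, which
    is sorted by gene id.  A tagSNP near k genes contributes to all k.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    per_gene: dict[str, list[tuple[MarkerRecord, int]]] = {}
    for tag, n_linked in tags:
        for gene_id in index.query(tag.chromosome, tag.position, window):
            per_gene.setdefault(gene_id, []).append((tag, n_linked))
    assignments: list[GeneAssignment] = []
    for gene_id in sorted(per_gene):
        hits = per_gene[gene_id]
        cands = [(t.effect, t.p_value, n, t.position) for t, n in hits]
        effect, p, total = resolve_gene_effect(cands)
        assignments.append(
            GeneAssignment(
                gene_id=gene_id,
                chromosome=index.genes[gene_id].chromosome,
                effect=effect,
                p_value=p,
                n_linked_snps=total,
                contributing_tags=[
                    (t.marker_id, t.effect, t.p_value, n) for t, n in hits
                ],
            )
        )
    return assignments
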