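"""Synthetic GWAS input generator with controllable pathway signal.

Builds complete, internally consistent input sets — association statistics,
allele effects, pairwise LD, GFF3 gene models and pathway definitions — so
every pipeline stage can be exercised without external data.  The layout
emulates a diploid crop GWAS: genes spaced along a few chromosomes, one
trait-associated SNP inside each gene, and extra intergenic SNPs arranged in
LD blocks.  One pathway may be *planted*: the SNPs of its genes draw their
effects from a shifted normal, creating a true enrichment signal of known
location and size.

Effects are N(0, σ) under the null and N(μ_shift, σ) for planted genes;
p-values are a monotone decreasing map of |effect| with small jitter, so
stronger effects always look more significant.  Within-block LD r² is
Uniform(lo, hi) and between-block r² Uniform(0, lo): with the linkage cutoff
set to ``lo``, the strict "exceeds" rule recovers the constructed blocks
exactly (almost surely).

What this generator does **not** emulate: population structure, minor-allele
frequency spectra, LD decay with distance, or genotyping error — passing
tests here demonstrate the bookkeeping and statistics, not robustness to
confounded real-world data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

from . import io as gio
from .models import GeneFeature, LDPair, MarkerRecord, PathwayDef

_BASES = ("A", "C", "G", "T")


@dataclass
class FixtureConfig:
    """Knobs for the synthetic dataset.

    Defaults give 20 disjoint pathways of 10 genes each (200 genes, 400
    SNPs over 2 chromosomes) with pathway ``PWY0001`` planted at a shift of
    two standard deviations — a moderate, recoverable signal.
    """

    n_chromosomes: int = 2
    n_snps: int = 400
    n_genes: int = 200
    n_pathways: int = 20
    genes_per_pathway: int = 10
    planted_pathway_id: Optional[str] = "PWY0001"
    effect_sd: float = 1.0
    mu_shift: float = 2.0            # planted-gene effect mean, in units of effect_sd
    ld_r2_lo: float = 0.8            # within-block r² ~ U(lo, hi); between ~ U(0, lo)
    ld_r2_hi: float = 1.0
    block_size_min: int = 1
    block_size_max: int = 5
    gene_length: int = 2_000
    gene_spacing: int = 10_000       # keeps the default 1 kb window unambiguous
    trait: str = "trait1"
    p_jitter: float = 0.05
    seed: int = 0
    effect_overrides: dict = field(default_factory=dict)   # marker_id -> effect
    p_overrides: dict = field(default_factory=dict)        # marker_id -> p

    def __post_init__(self) -> None:
        if self.n_snps < self.n_genes:
            raise ValueError("n_snps must be >= n_genes (one causal SNP per gene)")
        if self.n_pathways * self.genes_per_pathway > self.n_genes:
            raise ValueError("pathways require more genes than n_genes provides")


@dataclass
class Dataset:
    """An in-memory input set plus its ground-truth manifest."""

    markers: list[MarkerRecord]
    ld: dict[str, list[LDPair]]
    genes: list[GeneFeature]
    pathways: list[PathwayDef]
    manifest: dict


def _p_from_effect(abs_effect: float, sd: float, jitter: float, rng) -> float:
    """Monotone map |effect| → p, with multiplicative jitter, clipped to (0, 1]."""
    base = float(stats.norm.sf(abs_effect / sd))
    noisy = base * float(np.exp(rng.uniform(-jitter, jitter)))
    return float(np.clip(noisy, 1e-12, 1.0))


def generate_dataset(config: FixtureConfig) -> Dataset:
    """Deterministically build the full input set for ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genes: list[GeneFeature] = []
    markers: list[MarkerRecord] = []
    ld: dict[str, list[LDPair]] = {}
    snp_to_gene: dict[str, str] = {}
    true_blocks: list[list[str]] = []

    # pathways over the first n_pathways * genes_per_pathway genes, disjoint
    gene_ids = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    pathways = []
    for p in range(config.n_pathways):
        pid = f"PWY{p + 1:04d}"
        members = gene_ids[
            p * config.genes_per_pathway : (p + 1) * config.genes_per_pathway
        ]
        pathways.append(
            PathwayDef(pathway_id=pid, pathway_name=f"pathway {p + 1}", gene_ids=frozenset(members))
        )
    planted_genes: set[str] = set()
    if config.planted_pathway_id is not None:
        match = [p for p in pathways if p.pathway_id == config.planted_pathway_id]
        if not match:
            raise ValueError(
                f"planted pathway {config.planted_pathway_id!r} not among generated pathways"
            )
        planted_genes = set(match[0].gene_ids)

    # genes laid out chromosome by chromosome
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    chrom_of_gene: dict[str, str] = {}
    gene_span: dict[str, tuple[int, int]] = {}
    for i, gid in enumerate(gene_ids):
        chrom = f"chr{i // per_chrom + 1}"
        slot = i % per_chrom
        start = 1 + slot * (config.gene_length + config.gene_spacing)
        end = start + config.gene_length - 1
        genes.append(GeneFeature(gene_id=gid, chromosome=chrom, start=start, end=end))
        chrom_of_gene[gid] = chrom
        gene_span[gid] = (start, end)

    def _alleles() -> tuple[str, str]:
        a, b = rng.choice(4, size=2, replace=False)
        return _BASES[a], _BASES[b]

    def _make_marker(mid: str, chrom: str, pos: int, effect: float) -> MarkerRecord:
        effect = float(config.effect_overrides.get(mid, effect))
        abs_e = abs(effect)
        p = config.p_overrides.get(mid)
        if p is None:
            p = _p_from_effect(abs_e, config.effect_sd, config.p_jitter, rng)
        return MarkerRecord(
            marker_id=mid,
            chromosome=chrom,
            position=pos,
            trait=config.trait,
            p_value=float(p),
            marker_r2=float(rng.uniform(0.01, 0.5)),
            effect=effect,
            alleles=_alleles(),
        )

    # one causal SNP inside each gene
    for i, gid in enumerate(gene_ids):
        start, end = gene_span[gid]
        pos = int(rng.integers(start, end + 1))
        mu = config.mu_shift * config.effect_sd if gid in planted_genes else 0.0
        effect = float(rng.normal(mu, config.effect_sd))
        mid = f"snp{i + 1:05d}"
        markers.append(_make_marker(mid, chrom_of_gene[gid], pos, effect))
        snp_to_gene[mid] = gid

    # intergenic SNPs grouped into LD blocks, far from any gene
    n_extra = config.n_snps - config.n_genes
    chrom_names = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    extra_region_start = 1 + per_chrom * (config.gene_length + config.gene_spacing) + 100_000
    next_pos = {c: extra_region_start for c in chrom_names}
    idx = config.n_genes
    site_counter = {c: 0 for c in chrom_names}
    while idx < config.n_snps:
        chrom = chrom_names[idx % config.n_chromosomes]
        size = int(rng.integers(config.block_size_min, config.block_size_max + 1))
        size = min(size, config.n_snps - idx)
        block: list[MarkerRecord] = []
        for _ in range(size):
            pos = next_pos[chrom]
            next_pos[chrom] += int(rng.integers(50, 500))
            effect = float(rng.normal(0.0, config.effect_sd))
            mid = f"snp{idx + 1:05d}"
            block.append(_make_marker(mid, chrom, pos, effect))
            idx += 1
        next_pos[chrom] += 5_000  # gap before the next block
        markers.extend(block)
        if size > 1:
            true_blocks.append([m.marker_id for m in block])
        rows = ld.setdefault(chrom, [])
        # complete within-block LD above the lo bound
        for i_a in range(size):
            for i_b in range(i_a + 1, size):
                a, b = block[i_a], block[i_b]
                rows.append(
                    LDPair(
                        locus=chrom,
                        position_a=a.position,
                        position_b=b.position,
                        site_a=site_counter[chrom] + i_a,
                        site_b=site_counter[chrom] + i_b,
                        dist_bp=abs(b.position - a.position),
                        ld_r2=float(rng.uniform(config.ld_r2_lo, config.ld_r2_hi)),
                    )
                )
        # one sub-threshold pair bridging to the previous block on this chromosome
        prev = [
            m for m in markers[: len(markers) - size]
            if m.chromosome == chrom and m.marker_id not in snp_to_gene
        ]
        if prev:
            a = prev[-1]
            b = block[0]
            rows.append(
                LDPair(
                    locus=chrom,
                    position_a=a.position,
                    position_b=b.position,
                    site_a=site_counter[chrom] - 1,
                    site_b=site_counter[chrom],
                    dist_bp=abs(b.position - a.position),
                    ld_r2=float(rng.uniform(0.0, config.ld_r2_lo)),
                )
            )
        site_counter[chrom] += size

    markers.sort(key=lambda m: (m.chromosome, m.position))
    manifest = {
        "seed": config.seed,
        "trait": config.trait,
        "planted_pathway_id": config.planted_pathway_id,
        "planted_genes": sorted(planted_genes),
        "snp_to_gene": snp_to_gene,
        "true_blocks": true_blocks,
        "n_snps": config.n_snps,
        "n_genes": config.n_genes,
        "ld_cutoff_for_exact_recovery": config.ld_r2_lo,
    }
    return Dataset(markers=markers, ld=ld, genes=genes, pathways=pathways, manifest=manifest)


def write_dataset(dataset: Dataset, outdir: "Path | str") -> dict[str, Path]:
    """Write the five input files plus the ground-truth manifest.

    Returns a mapping of logical names to paths; all files re-read cleanly
    through :mod:`gwaspath.io`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stats": outdir / "stats.tsv",
        "effects": outdir / "effects.tsv",
        "ld": outdir / "ld.tsv",
        "gff": outdir / "genes.gff3",
        "pathways": outdir / "pathways.tsv",
        "manifest": outdir / "manifest.json",
    }
    gio.write_association_stats(dataset.markers, paths["stats"])
    gio.write_allele_effects(dataset.markers, paths["effects"])
    all_pairs = [p for chrom in sorted(dataset.ld) for p in dataset.ld[chrom]]
    gio.write_ld(all_pairs, paths["ld"])
    gio.write_gff_genes(dataset.genes, paths["gff"])
    gio.write_pathways(dataset.pathways, paths["pathways"])
    paths["manifest"].write_text(json.dumps(dataset.manifest, indent=2, sort_keys=True))
    return paths


def worked_toy() -> Dataset:
    """The four-gene, two-pathway worked example.

    Four unlinked SNPs sit inside four genes on one chromosome with effects
    3, 2, 1 and 0.5.  Pathway ``TOY_UP`` holds the two strongest genes, so
    under ``direction='increase'`` its running sum is (+0.6, +1.0, +0.5, 0)
    and its ES is exactly 1.0 with the peak at rank 2.
    """
    effects = [3.0, 2.0, 1.0, 0.5]
    genes = []
    markers = []
    for i, eff in enumerate(effects):
        gid = f"toy_gene{i + 1}"
        start = 1 + i * 10_000
        genes.append(GeneFeature(gene_id=gid, chromosome="chr1", start=start, end=start + 999))
        markers.append(
            MarkerRecord(
                marker_id=f"toy_snp{i + 1}",
                chromosome="chr1",
                position=start + 500,
                trait="toy_trait",
                p_value=0.01 * (i + 1),
                marker_r2=0.2,
                effect=eff,
                alleles=("A", "G"),
            )
        )
    pathways = [
        PathwayDef("TOY_UP", "toy upregulated pathway", frozenset({"toy_gene1", "toy_gene2"})),
        PathwayDef("TOY_BG", "toy background pathway", frozenset({"toy_gene3", "toy_gene4"})),
    ]
    manifest = {
        "planted_pathway_id": "TOY_UP",
        "expected_es": 1.0,
        "expected_peak_rank": 2,
        "snp_to_gene": {m.marker_id: g.gene_id for m, g in zip(markers, genes)},
        "true_blocks": [],
    }
    return Dataset(markers=markers, ld={}, genes=genes, pathways=pathways, manifest=manifest)
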