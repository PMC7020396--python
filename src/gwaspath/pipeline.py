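"""End-to-end orchestration: load → collapse → assign → score → plot.

The stages are pure library calls; this module wires them together, writes
the tabular outputs and rugplots, serializes intermediate results so stages
can be re-run individually, and logs the counts at every filtering step.
Identical configuration and seed give byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import enrichment, genes as gene_mapping, io as gio, linkage, viz
from .models import GeneAssignment, MarkerRecord, PathwayResult, RunningSum
from .synthetic import Dataset

logger = logging.getLogger("gwaspath")


@dataclass
class RunConfig:
    """Everything a run needs; YAML- and CLI-loadable."""

    stats: str
    effects: str
    ld: str
    gff: str
    pathways: str
    trait: Optional[str] = None
    r2_cutoff: float = 0.8
    window: int = 1_000
    min_genes: int = 5
    n_perm: int = 1_000
    direction: str = "increase"
    filter_mode: str = "q"
    filter_value: float = 0.05
    seed: int = 0
    workers: int = 1
    null_mode: str = "bootstrap"
    outdir: str = "gwaspath_out"
    plot_format: str = "png"

    def validate(self) -> None:
        for name in ("stats", "effects", "ld", "gff", "pathways"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        if not 0 <= self.r2_cutoff <= 1:
            raise ValueError("r2_cutoff must be in [0, 1]")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.direction not in enrichment.DIRECTIONS:
            raise ValueError(f"direction must be one of {enrichment.DIRECTIONS}")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


def analyse(
    markers: list[MarkerRecord],
    ld: dict,
    genes: list,
    pathways: list,
    *,
    r2_cutoff: float = 0.8,
    window: int = 1_000,
    min_genes: int = 5,
    n_perm: int = 1_000,
    direction: str = "increase",
    seed: int = 0,
    workers: int = 1,
    null_mode: str = "bootstrap",
) -> tuple[list[PathwayResult], list[GeneAssignment], list, int]:
    """In-memory core pipeline (no file I/O).

    Returns ``(results, assignments, tags, n_problematic_pairs)``.
    """
    graph = linkage.build_linkage_graph(ld, r2_cutoff)
    groups = linkage.partition_groups(graph, markers)
    tags, n_problematic = linkage.collapse_to_tagsnps(groups, markers)
    assignments = gene_mapping.assign_all_genes(tags, genes, window)
    if len(assignments) < 2:
        logger.warning("fewer than two genes received a tagSNP; no pathway scoring")
        return [], assignments, tags, n_problematic
    results = enrichment.score_pathways(
        assignments,
        pathways,
        min_genes=min_genes,
        n_perm=n_perm,
        seed=seed,
        direction=direction,
        workers=workers,
        null_mode=null_mode,
    )
    return results, assignments, tags, n_problematic


def analyse_dataset(dataset: Dataset, **kwargs):
    """Run :func:`analyse` on an in-memory synthetic dataset."""
    return analyse(
        dataset.markers, dataset.ld, dataset.genes, dataset.pathways, **kwargs
    )


def results_frame(results: list[PathwayResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "pathway_name": r.pathway_name,
                "n_genes": r.n_genes,
                "ES": r.es_observed,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "z": r.z,
                "p": r.p_value,
                "q": r.q_value,
            }
            for r in results
        ],
        columns=[
            "pathway_id", "pathway_name", "n_genes", "ES",
            "null_mean", "null_sd", "z", "p", "q",
        ],
    )


def assignments_frame(assignments: list[GeneAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "chromosome": a.chromosome,
                "effect": a.effect,
                "p": a.p_value,
                "n_linked_snps": a.n_linked_snps,
                "contributing_tags": ";".join(t[0] for t in a.contributing_tags),
            }
            for a in assignments
        ],
        columns=["gene_id", "chromosome", "effect", "p", "n_linked_snps", "contributing_tags"],
    )


def save_results(results: list[PathwayResult], path: "Path | str") -> None:
    """Serialize scored pathways (incl. running-sum traces) to JSON."""
    payload = []
    for r in results:
        payload.append(
            {
                "pathway_id": r.pathway_id,
                "pathway_name": r.pathway_name,
                "n_genes": r.n_genes,
                "es_observed": r.es_observed,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "z": r.z,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "degenerate_null": r.degenerate_null,
                "hit_ranks": r.hit_ranks,
                "running_sum": None
                if r.running_sum is None
                else {
                    "values": [float(v) for v in r.running_sum.values],
                    "peak_rank": r.running_sum.peak_rank,
                    "es": r.running_sum.es,
                },
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1))


def load_results(path: "Path | str") -> list[PathwayResult]:
    payload = json.loads(Path(path).read_text())
    results = []
    for d in payload:
        rs = d.pop("running_sum")
        results.append(
            PathwayResult(
                pathway_id=d["pathway_id"],
                pathway_name=d["pathway_name"],
                n_genes=d["n_genes"],
                es_observed=d["es_observed"],
                null_mean=d["null_mean"],
                null_sd=d["null_sd"],
                z=d["z"],
                p_value=d["p_value"],
                q_value=d["q_value"],
                degenerate_null=d["degenerate_null"],
                hit_ranks=d["hit_ranks"],
                running_sum=None
                if rs is None
                else RunningSum(
                    values=np.array(rs["values"]), peak_rank=rs["peak_rank"], es=rs["es"]
                ),
            )
        )
    return results


def replot(results_json: "Path | str", outdir: "Path | str", fmt: str = "png") -> list[Path]:
    """Re-run only the plotting stage from serialized results."""
    return viz.plot_all(load_results(results_json), outdir, fmt)


def run_full_analysis(config: RunConfig) -> list[PathwayResult]:
    """Execute the whole pipeline from files, writing all outputs.

    Writes, under ``config.outdir``: the pathway results table, the
    gene-assignment and tagSNP tables, serialized scored results, rugplots
    for pathways passing the filter, the effective configuration, a run
    summary with counts at every filter, and a log.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    handler.setLevel(logging.INFO)
    old_level = logger.level
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("effective config: %s", dataclasses.asdict(config))
        stats = gio.read_association_stats(config.stats, trait=config.trait)
        effects = gio.read_allele_effects(config.effects, trait=config.trait)
        n_stats_markers = stats["marker"].nunique()
        markers = gio.merge_and_filter(stats, effects)
        logger.info(
            "loaded %d markers from stats; %d retained after biallelic/R2 filters",
            n_stats_markers, len(markers),
        )
        ld = gio.read_ld(config.ld)
        gene_feats = gio.read_gff_genes(config.gff)
        pathway_defs = gio.read_pathways(config.pathways)
        logger.info(
            "loaded %d LD loci, %d genes, %d pathways",
            len(ld), len(gene_feats), len(pathway_defs),
        )

        results, assignments, tags, n_problematic = analyse(
            markers, ld, gene_feats, pathway_defs,
            r2_cutoff=config.r2_cutoff,
            window=config.window,
            min_genes=config.min_genes,
            n_perm=config.n_perm,
            direction=config.direction,
            seed=config.seed,
            workers=config.workers,
            null_mode=config.null_mode,
        )
        n_retained_pathways = len(results)
        logger.info(
            "%d tagSNPs, %d problematic pair(s) dropped, %d genes assigned, "
            "%d pathways scored (%d failed min_genes=%d)",
            len(tags), n_problematic, len(assignments), n_retained_pathways,
            len(pathway_defs) - n_retained_pathways, config.min_genes,
        )

        results_frame(results).to_csv(outdir / "pathway_results.tsv", sep="\t", index=False)
        assignments_frame(assignments).to_csv(
            outdir / "gene_assignments.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [
                {
                    "marker_id": t.marker_id,
                    "chromosome": t.chromosome,
                    "position": t.position,
                    "effect": t.effect,
                    "p": t.p_value,
                    "marker_r2": t.marker_r2,
                    "n_linked": n,
                }
                for t, n in tags
            ],
            columns=["marker_id", "chromosome", "position", "effect", "p", "marker_r2", "n_linked"],
        ).to_csv(outdir / "tagsnps.tsv", sep="\t", index=False)
        save_results(results, outdir / "pathway_results.json")

        selected = enrichment.filter_pathways(
            results, config.filter_mode, config.filter_value
        )
        plots = viz.plot_all(selected, outdir / "rugplots", config.plot_format)
        logger.info("%d pathway(s) passed the %s filter; %d rugplot(s) written",
                    len(selected), config.filter_mode, len(plots))

        (outdir / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))
        summary = {
            "n_markers_in_stats": int(n_stats_markers),
            "n_markers_retained": len(markers),
            "n_problematic_pairs": n_problematic,
            "n_tagsnps": len(tags),
            "n_genes_assigned": len(assignments),
            "n_pathways_defined": len(pathway_defs),
            "n_pathways_scored": n_retained_pathways,
            "n_pathways_selected": len(selected),
        }
        (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2))
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()
        logger.setLevel(old_level)
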