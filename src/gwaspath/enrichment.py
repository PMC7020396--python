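"""Pathway scoring: weighted running-sum enrichment against a resampled null.

Genes are ranked by their inherited effects from best to worst — descending
for traits where an *increase* is of interest, ascending for a *decrease*.
For each pathway a running sum walks down the ranking, rising by
``|e_i| / Σ_{hits}|e|`` at pathway genes and falling by ``1 / (N − N_hits)``
elsewhere; both step families total one, so the sum returns to zero at the
bottom of the list.  The enrichment score (ES) is the maximum of the running
sum.  Significance comes from re-scoring the same pathway geometry after
resampling the observed effect vector with replacement: the observed ES is
normalized by the null mean and standard deviation into a z-score, p is the
upper-tail normal probability, and q-values control the FDR across pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from scipy import stats

from .models import GeneAssignment, PathwayDef, PathwayResult, RunningSum

logger = logging.getLogger("gwaspath")

DIRECTIONS = ("increase", "decrease")


@dataclass
class RankedGeneList:
    """Genes ordered best-to-worst by effect for the chosen trait direction."""

    gene_ids: list[str]
    effects: np.ndarray
    direction: str

    def __len__(self) -> int:
        return len(self.gene_ids)


def rank_genes(assignments: list[GeneAssignment], direction: str) -> RankedGeneList:
    """Sort assigned genes by effect; ties are broken by gene id.

    ``direction='increase'`` puts the largest (most positive) effects first,
    ``'decrease'`` the smallest.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if len(assignments) < 2:
        raise ValueError("need at least two gene assignments to rank")
    sign = -1.0 if direction == "increase" else 1.0
    ordered = sorted(assignments, key=lambda a: (sign * a.effect, a.gene_id))
    return RankedGeneList(
        gene_ids=[a.gene_id for a in ordered],
        effects=np.array([a.effect for a in ordered], dtype=float),
        direction=direction,
    )


def _step_vector(abs_effects: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Per-rank increments: normalized |effect| at hits, uniform loss at misses."""
    n = hits.size
    n_hits = int(hits.sum())
    steps = np.full(n, -1.0 / (n - n_hits))
    denom = abs_effects[hits].sum()
    if denom > 0:
        steps[hits] = abs_effects[hits] / denom
    else:
        logger.info("running_sum: all hit effects are zero; using uniform hit steps")
        steps[hits] = 1.0 / n_hits
    return steps


def running_sum(ranked: RankedGeneList, pathway_genes: set[str]) -> RunningSum:
    """Running-sum trace and ES for one pathway over the ranked gene list."""
    hits = np.array([g in pathway_genes for g in ranked.gene_ids], dtype=bool)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("pathway has no genes in the ranking")
    if n_hits == len(ranked):
        raise ValueError("pathway covers the entire ranking; ES is undefined")
    values = np.cumsum(_step_vector(np.abs(ranked.effects), hits))
    peak = int(np.argmax(values))
    return RunningSum(values=values, peak_rank=peak + 1, es=float(values[peak]))


def apply_min_genes(
    pathways: list[PathwayDef],
    assignments: list[GeneAssignment],
    min_genes: int,
) -> list[PathwayDef]:
    """Keep pathways with at least ``min_genes`` genes in the ranked universe.

    Membership is counted after intersecting each pathway's gene set with
    the assigned genes, guarding the null normalization against small-sample
    bias.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    assigned = {a.gene_id for a in assignments}
    kept = [p for p in pathways if len(p.gene_ids & assigned) >= min_genes]
    if not kept:
        logger.warning("no pathway has >= %d assigned genes", min_genes)
    return kept


def _null_es_one(
    seed_seq: np.random.SeedSequence,
    effects: np.ndarray,
    membership: np.ndarray,
    descending: bool,
    replace: bool,
) -> np.ndarray:
    """ES of every pathway for one resampled effect vector.

    Effects are drawn from the observed vector (with replacement for the
    bootstrap null, a permutation otherwise), reassigned to the gene labels
    in fixed order, re-ranked, and re-scored.
    """
    rng = np.random.default_rng(seed_seq)
    n = effects.size
    if replace:
        sampled = rng.choice(effects, size=n, replace=True)
    else:
        sampled = rng.permutation(effects)
    key = -sampled if descending else sampled
    order = np.argsort(key, kind="stable")  # stable → gene-id tie-break
    abs_ranked = np.abs(sampled[order])
    hit = membership[:, order]  # (P, N) bool
    n_hits = hit.sum(axis=1)
    denom = hit @ abs_ranked
    steps = np.where(hit, abs_ranked[None, :], 0.0)
    safe = denom > 0
    steps[safe] /= denom[safe, None]
    if not safe.all():
        for i in np.nonzero(~safe)[0]:
            steps[i, hit[i]] = 1.0 / n_hits[i]
    miss_step = -1.0 / (n - n_hits)
    steps[~hit] = np.repeat(miss_step, n - n_hits)
    return steps.cumsum(axis=1).max(axis=1)


def sample_null_es(
    assignments: list[GeneAssignment],
    pathways: list[PathwayDef],
    n_perm: int,
    seed: int,
    direction: str,
    workers: int = 1,
    null_mode: str = "bootstrap",
) -> np.ndarray:
    """Null ES matrix of shape ``(len(pathways), n_perm)``.

    Each replicate draws a fresh effect vector (sampling the observed
    effects with replacement by default; ``null_mode='permutation'`` shuffles
    without replacement), then recomputes the ES of every pathway.  Each
    replicate owns a seed substream spawned from the master seed, so results
    are bit-identical for any ``workers`` count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if null_mode not in ("bootstrap", "permutation"):
        raise ValueError("null_mode must be 'bootstrap' or 'permutation'")
    gene_ids = sorted(a.gene_id for a in assignments)
    eff_by_gene = {a.gene_id: a.effect for a in assignments}
    effects = np.array([eff_by_gene[g] for g in gene_ids], dtype=float)
    membership = np.array(
        [[g in p.gene_ids for g in gene_ids] for p in pathways], dtype=bool
    )
    descending = direction == "increase"
    replace = null_mode == "bootstrap"
    children = np.random.SeedSequence(seed).spawn(n_perm)
    if workers == 1:
        cols = [
            _null_es_one(c, effects, membership, descending, replace) for c in children
        ]
    else:
        cols = Parallel(n_jobs=workers)(
            delayed(_null_es_one)(c, effects, membership, descending, replace)
            for c in children
        )
    return np.column_stack(cols)


def score_pathway(es_observed: float, null_samples: np.ndarray) -> tuple[float, float, bool]:
    """Normalize an observed ES against its null: ``(z, p, degenerate)``.

    ``z = (ES − mean(null)) / sd(null)`` with the sample (N−1) standard
    deviation; ``p`` is the upper-tail standard normal probability of z.
    A zero null sd is degenerate: p is 1 when the ES does not exceed the
    null mean and the smallest positive float otherwise.
    """
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size < 2:
        raise ValueError("need at least two null samples")
    mean = float(null_samples.mean())
    sd = float(null_samples.std(ddof=1))
    if sd == 0.0:
        if es_observed <= mean:
            return -np.inf if es_observed < mean else 0.0, 1.0, True
        return np.inf, float(np.finfo(float).tiny), True
    z = (es_observed - mean) / sd
    return float(z), float(stats.norm.sf(z)), False


def adjust_q(p_values: "np.ndarray | list[float]") -> np.ndarray:
    """FDR q-values across pathways.

    With at least 100 p-values, π₀ (the null proportion) is estimated by the
    Storey smoother — π₀(λ) = #{p > λ} / (m(1−λ)) over λ = 0.05…0.95, cubic
    polynomial smoothed and evaluated at the largest λ.  Otherwise, or if the
    estimate leaves (0, 1], π₀ = 1, which reduces to Benjamini–Hochberg.
    q-values are monotone non-decreasing in p-rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = 1.0
    if m >= 100:
        lambdas = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
        try:
            coeffs = np.polyfit(lambdas, pi0_lam, deg=3)
            est = float(np.polyval(coeffs, lambdas[-1]))
            if 0 < est <= 1:
                pi0 = est
            else:
                logger.info("adjust_q: pi0 estimate %.3f out of range; using 1", est)
        except np.linalg.LinAlgError:
            logger.info("adjust_q: pi0 smoothing failed; using 1")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_ranked = pi0 * m * ranked / np.arange(1, m + 1)
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q_ranked = np.clip(q_ranked, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_ranked
    return q


def score_pathways(
    assignments: list[GeneAssignment],
    pathways: list[PathwayDef],
    min_genes: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
    direction: str = "increase",
    workers: int = 1,
    null_mode: str = "bootstrap",
) -> list[PathwayResult]:
    """Full scoring pass: filter, observed ES, null, z/p/q.

    Returns one :class:`PathwayResult` per retained pathway, carrying the
    observed running-sum trace and the 1-based ranks of its member genes.
    """
    retained = apply_min_genes(pathways, assignments, min_genes)
    ranked = rank_genes(assignments, direction)
    universe = set(ranked.gene_ids)
    scorable = []
    for pw in retained:
        if pw.gene_ids >= universe:
            logger.warning(
                "pathway %s covers every ranked gene; skipped", pw.pathway_id
            )
            continue
        scorable.append(pw)
    if not scorable:
        return []
    null = sample_null_es(
        assignments, scorable, n_perm, seed, direction, workers, null_mode
    )
    results: list[PathwayResult] = []
    for i, pw in enumerate(scorable):
        rs = running_sum(ranked, set(pw.gene_ids))
        z, p, degenerate = score_pathway(rs.es, null[i])
        hit_ranks = [
            r + 1 for r, g in enumerate(ranked.gene_ids) if g in pw.gene_ids
        ]
        results.append(
            PathwayResult(
                pathway_id=pw.pathway_id,
                pathway_name=pw.pathway_name,
                n_genes=len(hit_ranks),
                es_observed=rs.es,
                null_mean=float(null[i].mean()),
                null_sd=float(null[i].std(ddof=1)),
                z=z,
                p_value=p,
                running_sum=rs,
                hit_ranks=hit_ranks,
                degenerate_null=degenerate,
            )
        )
    qs = adjust_q([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def filter_pathways(
    results: list[PathwayResult],
    mode: str = "q",
    threshold_or_n: float = 0.05,
) -> list[PathwayResult]:
    """Select pathways for reporting/plotting; output sorted by ascending p.

    ``mode`` is ``'p'`` or ``'q'`` (keep values ≤ threshold), ``'top_n'``
    (n smallest p, ties by pathway id) or ``'all'``.
    """
    by_p = sorted(results, key=lambda r: (r.p_value, r.pathway_id))
    if mode == "all":
        return by_p
    if mode == "p":
        return [r for r in by_p if r.p_value <= threshold_or_n]
    if mode == "q":
        return [r for r in by_p if r.q_value <= threshold_or_n]
    if mode == "top_n":
        n = int(threshold_or_n)
        if n > len(by_p):
            logger.warning("top_n=%d exceeds %d results; returning all", n, len(by_p))
        return by_p[:n]
    raise ValueError(f"unknown filter mode {mode!r}")
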