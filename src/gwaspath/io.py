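"""Readers and writers for the five input file families.

All tabular inputs are tab-delimited text in the TASSEL GLM/MLM dialects
(association statistics, allele effects, pairwise LD); genes come from GFF3
and pathways from a three-column tab-delimited file (pathway id, pathway
name, gene id; no header).  Column headers vary across TASSEL versions, so
every table reader accepts a ``columns`` mapping from canonical names to the
header names actually present; the defaults below match TASSEL 5 output.

Readers accept plain or gzip-compressed text.  Missing values are accepted
as "NA", "NaN" or the empty string.  All coordinates are 1-based inclusive,
matching GFF3.
"""

from __future__ import annotations

import gzip
import logging
from collections import OrderedDict
from os import PathLike
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

from .models import GeneFeature, LDPair, MarkerRecord, PathwayDef

logger = logging.getLogger("gwaspath")

PathType = Union[str, PathLike]

NA_VALUES = ["NA", "NaN", ""]

#: canonical -> TASSEL 5 header names
STATS_COLUMNS = {
    "trait": "Trait",
    "marker": "Marker",
    "chromosome": "Chr",
    "position": "Pos",
    "p_value": "p",
    "marker_r2": "marker_R2",
}
EFFECTS_COLUMNS = {
    "trait": "Trait",
    "marker": "Marker",
    "allele": "Allele",
    "effect": "Effect",
}
LD_COLUMNS = {
    "locus_a": "Locus1",
    "position_a": "Position1",
    "site_a": "Site1",
    "locus_b": "Locus2",
    "position_b": "Position2",
    "site_b": "Site2",
    "dist_bp": "Dist_bp",
    "ld_r2": "R^2",
}


class FormatError(ValueError):
    """A required column or field is missing or malformed."""


def _open_text(path: PathType, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_table(path: PathType, columns: dict, what: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype=str, na_values=NA_VALUES, keep_default_na=False
    )
    missing = [v for v in columns.values() if v not in df.columns]
    if missing:
        raise FormatError(
            f"{what} file {path} is missing required column(s): {', '.join(missing)}"
        )
    df = df[list(columns.values())].copy()
    df.columns = list(columns.keys())
    return df


def _coerce_numeric(
    df: pd.DataFrame, col: str, what: str, reject: bool = True
) -> pd.DataFrame:
    """Parse a string column as float; optionally drop unparseable rows."""
    def _to_float(value):
        # python float() is exact on repr output; pandas' fast parser is not
        try:
            return float(value)
        except (TypeError, ValueError):
            return np.nan

    raw = df[col]
    parsed = pd.Series([_to_float(v) for v in raw], index=raw.index, dtype=float)
    bad = parsed.isna() & raw.notna()  # present but unreadable
    if bad.any() and reject:
        logger.warning(
            "%s: dropping %d row(s) with unreadable %s values", what, int(bad.sum()), col
        )
        df = df[~bad].copy()
        parsed = parsed[~bad]
    df[col] = parsed
    return df


def read_association_stats(
    path: PathType,
    trait: Optional[str] = None,
    columns: Optional[dict] = None,
) -> pd.DataFrame:
    """Read a GLM/MLM association-statistics table.

    Returns one row per (marker, trait) with ``p_value`` and ``marker_r2``
    parsed as floats.  Rows for other traits are excluded when ``trait`` is
    given.  A missing ``marker_r2`` value is kept as NaN here and removed in
    :func:`merge_and_filter`; rows with unreadable position or p are dropped
    with a warning.
    """
    cols = dict(STATS_COLUMNS, **(columns or {}))
    df = _read_table(path, cols, "association statistics")
    if trait is not None:
        df = df[df["trait"] == trait].copy()
    df = _coerce_numeric(df, "position", "association statistics")
    df = _coerce_numeric(df, "p_value", "association statistics")
    df = _coerce_numeric(df, "marker_r2", "association statistics", reject=False)
    bad_p = (df["p_value"] <= 0) | (df["p_value"] > 1)
    if bad_p.any():
        logger.warning(
            "association statistics: dropping %d row(s) with p outside (0, 1]",
            int(bad_p.sum()),
        )
        df = df[~bad_p].copy()
    df["position"] = df["position"].astype(int)
    return df.reset_index(drop=True)


def read_allele_effects(
    path: PathType,
    trait: Optional[str] = None,
    columns: Optional[dict] = None,
) -> pd.DataFrame:
    """Read an allele-effects table: one row per (marker, allele).

    The signed effect is the magnitude of each SNP allele's effect on the
    trait.  File order is preserved — the first-nonzero collapsing convention
    in :func:`merge_and_filter` depends on it.
    """
    cols = dict(EFFECTS_COLUMNS, **(columns or {}))
    df = _read_table(path, cols, "allele effects")
    if trait is not None:
        df = df[df["trait"] == trait].copy()
    df = _coerce_numeric(df, "effect", "allele effects")
    return df.reset_index(drop=True)


def merge_and_filter(stats: pd.DataFrame, effects: pd.DataFrame) -> list[MarkerRecord]:
    """Join statistics and effects, apply the biallelic and R² filters.

    A marker is retained iff it has exactly two allele rows in ``effects``
    (biallelic) and a non-missing marker R² in ``stats``.  The two allele
    rows collapse to one signed effect: the first row in file order whose
    effect is nonzero (first row if both are zero).  Output is sorted by
    (chromosome, position).
    """
    stats_by_marker = stats.set_index("marker", drop=False)
    n_non_biallelic = 0
    n_missing_r2 = 0
    records: list[MarkerRecord] = []
    seen = set()
    for marker, grp in effects.groupby("marker", sort=False):
        seen.add(marker)
        if marker not in stats_by_marker.index:
            logger.warning("marker %s present in effects but absent from stats; dropped", marker)
            continue
        if len(grp) != 2:
            n_non_biallelic += 1
            continue
        srow = stats_by_marker.loc[marker]
        if isinstance(srow, pd.DataFrame):
            srow = srow.iloc[0]
        if pd.isna(srow["marker_r2"]):
            n_missing_r2 += 1
            continue
        effs = grp["effect"].to_numpy(dtype=float)
        alleles = tuple(grp["allele"].tolist())
        nonzero = np.nonzero(effs)[0]
        effect = float(effs[nonzero[0]]) if nonzero.size else float(effs[0])
        records.append(
            MarkerRecord(
                marker_id=str(marker),
                chromosome=str(srow["chromosome"]),
                position=int(srow["position"]),
                trait=str(srow["trait"]),
                p_value=float(srow["p_value"]),
                marker_r2=float(srow["marker_r2"]),
                effect=effect,
                alleles=alleles,  # type: ignore[arg-type]
            )
        )
    # markers in stats with no effect rows at all also fail the biallelic filter
    n_no_effects = int((~stats["marker"].isin(seen)).sum())
    n_non_biallelic += n_no_effects
    if n_non_biallelic:
        logger.info("merge_and_filter: %d marker(s) dropped as non-biallelic", n_non_biallelic)
    if n_missing_r2:
        logger.info("merge_and_filter: %d marker(s) dropped for missing R2", n_missing_r2)
    records.sort(key=lambda m: (m.chromosome, m.position))
    return records


def read_ld(
    path: PathType, columns: Optional[dict] = None
) -> "OrderedDict[str, list[LDPair]]":
    """Read a TASSEL pairwise-LD table, keyed by locus.

    Inter-locus rows (Locus1 != Locus2) are dropped, as are rows with a
    missing LD R²; only the locus, positions, sites, distance and R² columns
    are retained.
    """
    cols = dict(LD_COLUMNS, **(columns or {}))
    df = _read_table(path, cols, "LD")
    n_total = len(df)
    df = df[df["locus_a"] == df["locus_b"]].copy()
    n_inter = n_total - len(df)
    if n_inter:
        logger.info("LD: dropped %d inter-locus row(s)", n_inter)
    for col in ("position_a", "position_b", "site_a", "site_b", "dist_bp"):
        df = _coerce_numeric(df, col, "LD")
    df = _coerce_numeric(df, "ld_r2", "LD", reject=False)
    n_na = int(df["ld_r2"].isna().sum())
    if n_na:
        logger.info("LD: dropped %d row(s) with missing R2", n_na)
        df = df[df["ld_r2"].notna()].copy()
    if df.empty and n_total:
        logger.warning("LD: no intra-locus rows with valid R2 remain")
    grouped: OrderedDict[str, list[LDPair]] = OrderedDict()
    for row in df.itertuples(index=False):
        pair = LDPair(
            locus=str(row.locus_a),
            position_a=int(row.position_a),
            position_b=int(row.position_b),
            site_a=int(row.site_a),
            site_b=int(row.site_b),
            dist_bp=int(row.dist_bp),
            ld_r2=float(row.ld_r2),
        )
        grouped.setdefault(pair.locus, []).append(pair)
    return grouped


def read_gff_genes(path: PathType) -> list[GeneFeature]:
    """Extract gene features from a GFF3 file.

    Only rows of feature type ``gene`` are kept; each must carry an ``ID``
    attribute.  Malformed lines are fatal with their line number.
    """
    genes: list[GeneFeature] = []
    seen_ids: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise FormatError(f"{path}:{lineno}: malformed GFF3 line (need 9 fields)")
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise FormatError(f"{path}:{lineno}: malformed GFF3 line: {exc}") from exc
            if feat.featuretype != "gene":
                continue
            if "ID" not in feat.attributes:
                raise FormatError(f"{path}:{lineno}: gene feature lacks an ID attribute")
            gene_id = feat.attributes["ID"][0]
            if gene_id in seen_ids:
                raise FormatError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen_ids.add(gene_id)
            genes.append(
                GeneFeature(
                    gene_id=gene_id,
                    chromosome=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand or ".",
                )
            )
    return genes


def read_pathways(path: PathType) -> list[PathwayDef]:
    """Read a pathway definition file: one line per (pathway, gene).

    Three tab-separated columns — pathway id, pathway name, gene id — with
    no header.  Duplicate (pathway, gene) lines are deduplicated with a
    warning; a line with fewer than three fields is fatal.
    """
    by_id: OrderedDict[str, tuple[str, list[str]]] = OrderedDict()
    n_dup = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            pid, pname, gene = fields[0], fields[1], fields[2]
            if pid not in by_id:
                by_id[pid] = (pname, [])
            if gene in by_id[pid][1]:
                n_dup += 1
                continue
            by_id[pid][1].append(gene)
    if n_dup:
        logger.warning("pathways: deduplicated %d repeated (pathway, gene) line(s)", n_dup)
    return [
        PathwayDef(pathway_id=pid, pathway_name=name, gene_ids=frozenset(genes))
        for pid, (name, genes) in by_id.items()
    ]


# ---------------------------------------------------------------------------
# writers (used by the synthetic-data generator and for round-trip checks)

def write_association_stats(
    markers: Iterable[MarkerRecord], path: PathType, columns: Optional[dict] = None
) -> None:
    cols = dict(STATS_COLUMNS, **(columns or {}))
    rows = [
        {
            cols["trait"]: m.trait,
            cols["marker"]: m.marker_id,
            cols["chromosome"]: m.chromosome,
            cols["position"]: m.position,
            cols["p_value"]: repr(m.p_value),
            cols["marker_r2"]: repr(m.marker_r2),
        }
        for m in markers
    ]
    pd.DataFrame(rows, columns=list(cols.values())).to_csv(path, sep="\t", index=False)


def write_allele_effects(
    markers: Iterable[MarkerRecord], path: PathType, columns: Optional[dict] = None
) -> None:
    """Write two allele rows per marker: (allele1, effect), (allele2, 0).

    The first row carries the marker's signed effect, so re-reading under the
    first-nonzero convention reproduces it exactly.
    """
    cols = dict(EFFECTS_COLUMNS, **(columns or {}))
    rows = []
    for m in markers:
        rows.append(
            {cols["trait"]: m.trait, cols["marker"]: m.marker_id,
             cols["allele"]: m.alleles[0], cols["effect"]: repr(m.effect)}
        )
        rows.append(
            {cols["trait"]: m.trait, cols["marker"]: m.marker_id,
             cols["allele"]: m.alleles[1], cols["effect"]: repr(0.0)}
        )
    pd.DataFrame(rows, columns=list(cols.values())).to_csv(path, sep="\t", index=False)


def write_ld(
    pairs: Iterable[LDPair], path: PathType, columns: Optional[dict] = None
) -> None:
    cols = dict(LD_COLUMNS, **(columns or {}))
    rows = [
        {
            cols["locus_a"]: p.locus,
            cols["position_a"]: p.position_a,
            cols["site_a"]: p.site_a,
            cols["locus_b"]: p.locus,
            cols["position_b"]: p.position_b,
            cols["site_b"]: p.site_b,
            cols["dist_bp"]: p.dist_bp,
            cols["ld_r2"]: repr(p.ld_r2),
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=list(cols.values())).to_csv(path, sep="\t", index=False)


def write_gff_genes(genes: Iterable[GeneFeature], path: PathType) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.chromosome,
                        "gwaspath",
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


def write_pathways(pathways: Iterable[PathwayDef], path: PathType) -> None:
    with _open_text(path, "wt") as fh:
        for pw in pathways:
            for gene in sorted(pw.gene_ids):
                fh.write(f"{pw.pathway_id}\t{pw.pathway_name}\t{gene}\n")
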