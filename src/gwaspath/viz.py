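"""Rugplot rendering for scored pathways.

One figure per pathway: the running-sum trace over gene rank, a vertical
line at the ES peak, and hatch marks along the top edge at the ranks of the
pathway's genes.  Rendering consumes only the stored trace and membership
ranks — statistics are never recomputed here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless backend; figures only ever go to files
import matplotlib.pyplot as plt

from .models import PathwayResult

logger = logging.getLogger("gwaspath")

FORMATS = ("png", "svg", "pdf")


@dataclass
class RugplotStyle:
    """Fixed figure geometry and colors (unstyled by the method itself)."""

    figsize: tuple[float, float] = (8.0, 4.5)
    trace_color: str = "#1f77b4"
    peak_color: str = "#d62728"
    hatch_color: str = "black"
    hatch_height: float = 0.04  # fraction of axes height
    dpi: int = 150


@dataclass
class RugplotSpec:
    """Everything the renderer needs, extracted from a PathwayResult."""

    x: list[int]
    y: list[float]
    peak_x: int
    hatch_positions: list[int]
    title: str
    out_path: Path
    style: RugplotStyle = field(default_factory=RugplotStyle)


def safe_filename(name: str) -> str:
    """Replace filesystem-unsafe characters with underscores."""
    return re.sub(r"[^A-Za-z0-9._-]", "_", name)


def spec_from_result(
    result: PathwayResult, out_dir: Path, fmt: str = "png"
) -> RugplotSpec:
    if result.running_sum is None or result.hit_ranks is None:
        raise ValueError(f"pathway {result.pathway_id} carries no running sum")
    values = result.running_sum.values
    return RugplotSpec(
        x=list(range(1, len(values) + 1)),
        y=list(values),
        peak_x=result.running_sum.peak_rank,
        hatch_positions=list(result.hit_ranks),
        title=f"{result.pathway_name} ({result.pathway_id})",
        out_path=Path(out_dir) / f"{safe_filename(result.pathway_id)}.{fmt}",
    )


def plot_rugplot(result: PathwayResult, out_path: "Path | str", fmt: str = "png") -> Path:
    """Render one pathway's rugplot to ``out_path`` (a file or directory)."""
    if fmt not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}")
    out_path = Path(out_path)
    if out_path.is_dir():
        spec = spec_from_result(result, out_path, fmt)
    else:
        spec = spec_from_result(result, out_path.parent, fmt)
        spec.out_path = out_path
    return render(spec)


def render(spec: RugplotSpec) -> Path:
    st = spec.style
    fig, ax = plt.subplots(figsize=st.figsize)
    ax.plot(spec.x, spec.y, color=st.trace_color, lw=1.5)
    ax.axvline(spec.peak_x, color=st.peak_color, lw=1.0, ls="--")
    ax.axhline(0.0, color="gray", lw=0.5)
    for rank in spec.hatch_positions:
        ax.axvline(
            rank,
            ymin=1.0 - st.hatch_height,
            ymax=1.0,
            color=st.hatch_color,
            lw=1.0,
        )
    ax.set_xlabel("gene effect rank")
    ax.set_ylabel("ES running sum")
    ax.set_title(spec.title)
    ax.set_xlim(1, max(spec.x))
    fig.tight_layout()
    fig.savefig(spec.out_path, dpi=st.dpi)
    plt.close(fig)
    return spec.out_path


def plot_all(
    results: list[PathwayResult], out_dir: "Path | str", fmt: str = "png"
) -> list[Path]:
    """One rugplot per result under ``out_dir``; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not results:
        logger.info("viz: no pathways to plot")
        return []
    return [plot_rugplot(r, out_dir, fmt) for r in results]
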