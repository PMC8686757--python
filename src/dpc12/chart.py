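"""Rendering a distance profile as the 12-subchart DPC12 figure.

The chart is a 4 x 3 grid of bar subcharts — rows TOP (TL, TF, TR), LEFT
(LF, L, LB), RIGHT (RF, R, RB), BOTTOM (BL, BB, BR) — sharing one distance
axis.  Within a subchart every object present in that cone gets a vertical
bar at its fixed slot spanning [min, max] anchor distance, filled with a
discrete sequential colour (light yellow to dark brown) encoding the
decile of the object fraction inside the cone.  Absent objects leave their
slot empty, so subcharts are directly comparable across the grid.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import to_hex
from matplotlib.patches import Patch

from .conification import CANONICAL_ORDER
from .profiles import DistanceProfile

__all__ = ["ColorScale", "ChartSpec", "fraction_to_bin", "render_dpc12", "render_guides"]

#: Default 4x3 grid: one row per direction group.
DEFAULT_GRID: tuple[tuple[str, ...], ...] = (
    ("TL", "TF", "TR"),
    ("LF", "L", "LB"),
    ("RF", "R", "RB"),
    ("BL", "BB", "BR"),
)

# Deterministic vector output: fixed hash salt, no timestamps.
_DETERMINISTIC_RC = {
    "svg.hashsalt": "dpc12",
    "pdf.compression": 0,
    "figure.dpi": 100,
    "font.family": "DejaVu Sans",
    "font.size": 8,
}


@dataclass(frozen=True)
class ColorScale:
    """Discrete sequential colour scale over fraction bins.

    ``bins`` are the right-closed intervals ``(k/n, (k+1)/n]``; fraction 0
    never occurs (objects absent from a cone get no bar).  Colours come
    from a sequential colormap and are strictly ordered light to dark.
    """

    bin_count: int = 10
    palette: str = "YlOrBr"
    colors: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self):
        if self.bin_count < 1:
            raise ValueError("bin_count must be >= 1")
        cmap = plt.get_cmap(self.palette)
        cols = tuple(
            to_hex(cmap(x)) for x in np.linspace(0.15, 1.0, self.bin_count)
        )
        object.__setattr__(self, "colors", cols)

    @property
    def bins(self) -> list[tuple[float, float]]:
        edges = np.linspace(0.0, 1.0, self.bin_count + 1)
        return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]

    def color_for(self, fraction: float) -> str:
        return self.colors[fraction_to_bin(fraction, self)]


def fraction_to_bin(fraction: float, scale: ColorScale | None = None) -> int:
    """Index of the right-closed fraction bin containing ``fraction``.

    With the default 10 bins the intervals are the deciles (0,0.1], ...,
    (0.9,1]; e.g. 0.95 falls in the top "90-100%" bin.
    """
    if scale is None:
        scale = ColorScale()
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    # upper edges; 'left' keeps f == edge in the lower (right-closed) bin
    edges = np.linspace(0.0, 1.0, scale.bin_count + 1)[1:-1]
    return int(np.searchsorted(edges, fraction, side="left"))


@dataclass
class ChartSpec:
    """Layout and style of a DPC12 figure."""

    grid: tuple[tuple[str, ...], ...] = DEFAULT_GRID
    y_max: float | None = None  # default: envelope diameter or global max
    scale: ColorScale = field(default_factory=ColorScale)
    title: str | None = None
    bar_width: float = 0.7
    figsize: tuple[float, float] = (9.0, 10.0)

    def __post_init__(self):
        labels = [lab for row in self.grid for lab in row]
        if sorted(labels) != sorted(CANONICAL_ORDER):
            raise ValueError("grid must contain each cone label exactly once")


def _resolve_ymax(profile: DistanceProfile, spec: ChartSpec) -> float:
    if spec.y_max is not None:
        if spec.y_max < profile.max_distance():
            raise ValueError(
                f"y_max {spec.y_max} is below the largest profile distance "
                f"{profile.max_distance():.4g}"
            )
        return float(spec.y_max)
    if profile.envelope_radius is not None:
        return 2.0 * profile.envelope_radius
    return float(profile.max_distance())


def render_dpc12(
    profile: DistanceProfile,
    spec: ChartSpec | None = None,
    out: str | None = None,
):
    """Render a distance profile as the 12-subchart figure.

    Returns the matplotlib Figure; if ``out`` is given the figure is also
    written there (format from the extension: png, svg or pdf).  Bars with
    min == max (single-point objects) are drawn as minimal-thickness ticks
    so they stay visible.  Rendering is deterministic: identical profile
    and spec give byte-identical SVG output.
    """
    if spec is None:
        spec = ChartSpec()
    y_max = _resolve_ymax(profile, spec)
    order = profile.object_order
    nrow, ncol = len(spec.grid), len(spec.grid[0])

    with plt.rc_context(_DETERMINISTIC_RC):
        fig, axes = plt.subplots(
            nrow, ncol, figsize=spec.figsize, sharey=True, squeeze=False
        )
        fig._dpc12_axes = {}
        fig._dpc12_ymax = y_max
        tick = max(y_max * 0.004, 1e-12)  # visible span for min == max bars
        for (r, c), lab in zip(
            [(r, c) for r in range(nrow) for c in range(ncol)],
            [lab for row in spec.grid for lab in row],
        ):
            ax = axes[r][c]
            fig._dpc12_axes[lab] = ax
            for slot, obj in enumerate(order):
                entry = profile.entries.get((lab, obj))
                if entry is None:
                    continue  # empty slot: object absent from this cone
                height = max(entry.max_dist - entry.min_dist, tick)
                ax.bar(
                    slot,
                    height,
                    bottom=entry.min_dist,
                    width=spec.bar_width,
                    color=spec.scale.color_for(entry.fraction),
                    edgecolor="black",
                    linewidth=0.4,
                )
            ax.set_title(lab, fontsize=9)
            ax.set_xlim(-0.7, len(order) - 0.3)
            ax.set_ylim(0.0, y_max)
            ax.set_xticks(range(len(order)))
            ax.set_xticklabels(order, rotation=90, fontsize=6)
            if c == 0:
                ax.set_ylabel(f"distance [{profile.units}]")
        handles = [
            Patch(facecolor=col, edgecolor="black", linewidth=0.3,
                  label=f"{int(round(a * 100))}–{int(round(b * 100))}%")
            for (a, b), col in zip(spec.scale.bins, spec.scale.colors)
        ]
        fig.legend(
            handles=handles,
            loc="lower center",
            ncol=min(len(handles), 5),
            fontsize=6,
            title="fraction of object in cone",
            title_fontsize=7,
        )
        fig.suptitle(
            spec.title
            if spec.title is not None
            else f"DPC12 — central object {profile.central_object_id}",
            fontsize=11,
        )
        fig.tight_layout(rect=(0, 0.07, 1, 0.97))
        if out is not None:
            save_chart(fig, out)
    return fig


def render_guides(fig, levels) -> None:
    """Draw horizontal ruler-guide baselines across all 12 subcharts.

    ``levels`` are distances; each must lie within [0, y_max].  The input
    order is irrelevant.  An empty list leaves the chart unchanged.
    """
    levels = sorted(float(v) for v in levels)
    y_max = getattr(fig, "_dpc12_ymax", None)
    if y_max is None:
        raise ValueError("figure was not produced by render_dpc12")
    for v in levels:
        if not 0.0 <= v <= y_max:
            raise ValueError(f"guide level {v} outside [0, {y_max}]")
    for ax in fig._dpc12_axes.values():
        for v in levels:
            ax.axhline(v, color="tab:blue", linewidth=0.8, zorder=0)


def save_chart(fig, out: str) -> None:
    """Write the figure; format from the file extension (png/svg/pdf)."""
    fmt = str(out).rsplit(".", 1)[-1].lower()
    if fmt not in {"png", "svg", "pdf"}:
        raise ValueError(f"unknown chart format {fmt!r} (use png, svg or pdf)")
    with plt.rc_context(_DETERMINISTIC_RC):
        fig.savefig(out, format=fmt, metadata=_no_date_metadata(fmt))


def _no_date_metadata(fmt: str):
    if fmt == "svg":
        return {"Date": None}
    if fmt == "pdf":
        return {"CreationDate": None}
    return None


def chart_svg_bytes(profile: DistanceProfile, spec: ChartSpec | None = None) -> bytes:
    """Render to SVG in memory (deterministic; used for stability checks)."""
    fig = render_dpc12(profile, spec)
    buf = io.BytesIO()
    with plt.rc_context(_DETERMINISTIC_RC):
        fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()
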