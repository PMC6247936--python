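"""The five plot types as pure functions from data to figure files.

Every function writes the figure to the given path (format chosen by the
file extension: png/svg/pdf) and returns the matplotlib ``Figure`` so
tests can assert on structural metadata (axis sizes, wedge counts, legend
entries) instead of pixels.  Completeness fractions share one fixed
colour scale over [0, 1] across the heatmap and the sunburst.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")  # headless; never require a display

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import cm, colors
from matplotlib.patches import Wedge

from .completeness import MCFMatrix
from .errors import EmptyMatrix, RaggedHierarchy, UnassignedRow

__all__ = [
    "MCF_CMAP",
    "MCF_NORM",
    "plot_heatmap",
    "plot_variance_boxplot",
    "plot_scatter",
    "plot_scatter_by_factors",
    "SunburstColorMode",
    "SunburstSpec",
    "plot_sunburst",
]

#: One perceptually-uniform [0, 1] colour mapping for all mcf figures.
MCF_CMAP = plt.get_cmap("viridis")
MCF_NORM = colors.Normalize(vmin=0.0, vmax=1.0)


def _as_frame(m) -> pd.DataFrame:
    df = m.values if isinstance(m, MCFMatrix) else pd.DataFrame(m)
    if df.size == 0:
        raise EmptyMatrix("matrix is empty")
    return df


def _save(fig, path, dpi):
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def plot_heatmap(mcf, path, *, dpi: int = 150, cmap=MCF_CMAP):
    """Colour-mapped completeness matrix: genomes on y, modules on x.

    The colour scale is fixed to [0, 1]; values outside are rejected by
    the matrix container before rendering.
    """
    df = _as_frame(mcf)
    arr = df.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("completeness values must lie in [0, 1]")
    h = max(2.5, 0.3 * df.shape[0] + 1.5)
    w = max(3.5, 0.45 * df.shape[1] + 2.0)
    fig, ax = plt.subplots(figsize=(w, h))
    im = ax.imshow(arr, cmap=cmap, norm=MCF_NORM, aspect="auto")
    ax.set_xticks(range(df.shape[1]), labels=df.columns, rotation=90)
    ax.set_yticks(range(df.shape[0]), labels=df.index)
    ax.set_xlabel("module")
    ax.set_ylabel("genome")
    fig.colorbar(im, ax=ax, label="mcf")
    _save(fig, path, dpi)
    return fig


def plot_variance_boxplot(mcf, path, *, dpi: int = 150):
    """One box of completeness values per module column."""
    df = _as_frame(mcf)
    fig, ax = plt.subplots(figsize=(max(3.5, 0.5 * df.shape[1] + 1.5), 3.5))
    ax.boxplot([df[c].to_numpy() for c in df.columns], tick_labels=list(df.columns))
    ax.set_ylabel("mcf")
    ax.set_xlabel("module")
    ax.set_ylim(-0.05, 1.05)
    ax.tick_params(axis="x", rotation=90)
    _save(fig, path, dpi)
    return fig


def plot_scatter(values: pd.Series | Mapping[str, float], path, *,
                 ylabel: str = "value", dpi: int = 150):
    """Scatter of one numeric value per category (e.g. SD per module)."""
    series = pd.Series(values, dtype=float)
    if series.empty:
        raise EmptyMatrix("no values to plot")
    fig, ax = plt.subplots(figsize=(max(3.5, 0.4 * len(series) + 1.5), 3.2))
    ax.scatter(range(len(series)), series.to_numpy())
    ax.set_xticks(range(len(series)), labels=list(series.index), rotation=90)
    ax.set_ylabel(ylabel)
    _save(fig, path, dpi)
    return fig


def plot_scatter_by_factors(points: pd.DataFrame, factor: Mapping[str, str],
                            path, *, dpi: int = 150):
    """2-D scatter of points coloured by factor group, with a legend."""
    if points.empty:
        raise EmptyMatrix("no points to plot")
    missing = [r for r in points.index if r not in factor]
    if missing:
        raise UnassignedRow(f"rows without a group: {missing}")
    xs = points.iloc[:, 0]
    ys = points.iloc[:, 1] if points.shape[1] > 1 else pd.Series(
        np.zeros(len(points)), index=points.index
    )
    groups = pd.Series({r: factor[r] for r in points.index})
    fig, ax = plt.subplots(figsize=(4.5, 3.8))
    for name in groups.unique():
        mask = groups == name
        ax.scatter(xs[mask], ys[mask], label=str(name))
    ax.set_xlabel(points.columns[0])
    ax.set_ylabel(points.columns[1] if points.shape[1] > 1 else "")
    ax.legend(title="group", fontsize="small")
    _save(fig, path, dpi)
    return fig


class SunburstColorMode(enum.Enum):
    BY_COUNT = "count"
    BY_VALUE = "value"


@dataclass
class SunburstSpec:
    """Hierarchical categorical data for a sunburst (dart-style) chart.

    ``hierarchy`` lists one path per leaf, most general level first (e.g.
    module class, subclass, module id); ``leaf_values`` pairs each path
    with a number (a count or an mcf).  Paths of unequal depth raise
    :class:`RaggedHierarchy` unless ``pad=True`` pads short paths with
    empty labels.
    """

    hierarchy: list[tuple[str, ...]]
    leaf_values: list[float]
    color_mode: SunburstColorMode = SunburstColorMode.BY_VALUE
    pad: bool = False
    depth: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.hierarchy) != len(self.leaf_values):
            raise ValueError("one value per hierarchy path required")
        if not self.hierarchy:
            raise EmptyMatrix("empty hierarchy")
        depths = {len(p) for p in self.hierarchy}
        if len(depths) > 1:
            if not self.pad:
                raise RaggedHierarchy(
                    f"hierarchy paths have differing depths {sorted(depths)}"
                )
            depth = max(depths)
            self.hierarchy = [
                tuple(p) + ("",) * (depth - len(p)) for p in self.hierarchy
            ]
        else:
            self.hierarchy = [tuple(p) for p in self.hierarchy]
        if not all(np.isfinite(self.leaf_values)):
            raise ValueError("leaf values must be finite")
        self.depth = len(self.hierarchy[0])


def plot_sunburst(spec: SunburstSpec, path, *, dpi: int = 150,
                  cmap=MCF_CMAP):
    """Ring chart of a hierarchy: inner ring most general, outer ring the
    leaves.

    Each leaf occupies an equal angular span; inner-ring wedges span their
    descendants.  Inner rings are coloured neutrally; the final ring is
    coloured by leaf count share per label (BY_COUNT) or by the supplied
    values on the fixed [0, 1] mcf scale (BY_VALUE).
    """
    n = len(spec.hierarchy)
    angles = np.linspace(0, 360, n + 1)
    fig, ax = plt.subplots(figsize=(5, 5), subplot_kw={"aspect": "equal"})
    ring_width = 1.0 / spec.depth
    neutral = plt.get_cmap("Pastel1")

    for level in range(spec.depth):
        r_outer = ring_width * (level + 1)
        # group consecutive leaves sharing the same path prefix
        start = 0
        seen_labels: list[str] = []
        while start < n:
            prefix = spec.hierarchy[start][: level + 1]
            end = start
            while end < n and spec.hierarchy[end][: level + 1] == prefix:
                end += 1
            label = prefix[-1]
            if level == spec.depth - 1:
                if spec.color_mode is SunburstColorMode.BY_VALUE:
                    color = cmap(MCF_NORM(spec.leaf_values[start]))
                else:
                    color = cmap(MCF_NORM((end - start) / n))
            else:
                if label not in seen_labels:
                    seen_labels.append(label)
                color = neutral(seen_labels.index(label) % 9)
            wedge = Wedge(
                (0, 0),
                r_outer,
                angles[start],
                angles[end],
                width=ring_width,
                facecolor=color,
                edgecolor="white",
                linewidth=1.0,
            )
            wedge.set_gid(f"ring{level}:{label}")
            ax.add_patch(wedge)
            if label:
                mid = np.deg2rad((angles[start] + angles[end]) / 2)
                r_text = r_outer - ring_width / 2
                ax.text(
                    r_text * np.cos(mid),
                    r_text * np.sin(mid),
                    label,
                    ha="center",
                    va="center",
                    fontsize=7,
                )
            start = end
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.axis("off")
    if spec.color_mode is SunburstColorMode.BY_VALUE:
        sm = cm.ScalarMappable(norm=MCF_NORM, cmap=cmap)
        fig.colorbar(sm, ax=ax, label="mcf", shrink=0.7)
    _save(fig, path, dpi)
    return fig
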