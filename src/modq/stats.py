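"""Analysis layer over completeness matrices.

The central spread statistic is the mean pairwise Euclidean distance of a
set of points (typically principal-component scores of genomes): the sum
of all pairwise distances divided by the number of pairs, p(p-1)/2.  It is
used globally and per factor group (e.g. per genus) as a proxy for
within-group functional variability.

Also here: per-module standard deviations, zero-variance module
detection, factor-grouped mean completeness, and the automated report
that ties the analyses and figures together.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .errors import (
    InsufficientPoints,
    InsufficientRows,
    SingletonGroupWarning,
    UnassignedRow,
)
from .completeness import MCFMatrix

__all__ = [
    "mean_euclidean_distance",
    "grouped_mean_distance",
    "zero_variance_modules",
    "column_sd",
    "group_mean_mcf",
    "pca_scores",
    "build_report",
]


def _as_frame(m: MCFMatrix | pd.DataFrame) -> pd.DataFrame:
    return m.values if isinstance(m, MCFMatrix) else m


def _check_factor(index: pd.Index, factor: Mapping[str, str]) -> pd.Series:
    missing = [r for r in index if r not in factor]
    if missing:
        raise UnassignedRow(f"rows without a group: {missing}")
    return pd.Series({r: factor[r] for r in index})


def mean_euclidean_distance(points: pd.DataFrame | np.ndarray) -> float:
    """Mean pairwise Euclidean distance of p n-dimensional points.

    Sum of the p(p-1)/2 pairwise distances divided by the number of
    pairs.  Rows are points, columns coordinates.  Raises
    :class:`InsufficientPoints` for fewer than two points.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] < 2:
        raise InsufficientPoints(
            f"need at least 2 points, got {arr.shape[0]}"
        )
    if not np.isfinite(arr).all():
        raise ValueError("coordinates must be finite")
    return float(pdist(arr).mean())


def grouped_mean_distance(
    points: pd.DataFrame, factor: Mapping[str, str]
) -> dict[str, float]:
    """Mean Euclidean distance within each factor group.

    ``factor`` maps every row label to a group.  Singleton groups have no
    pairwise distance; they are reported as NaN with a warning rather
    than 0, which would falsely signal perfect tightness.  Group order is
    first appearance in the row order.
    """
    groups = _check_factor(points.index, factor)
    out: dict[str, float] = {}
    for name in groups.unique():
        rows = points.loc[groups == name]
        if len(rows) < 2:
            warnings.warn(
                f"group {name!r} has a single member; spread undefined",
                SingletonGroupWarning,
                stacklevel=2,
            )
            out[name] = float("nan")
        else:
            out[name] = mean_euclidean_distance(rows)
    return out


def zero_variance_modules(mcf: MCFMatrix | pd.DataFrame) -> list[str]:
    """Modules whose completeness is identical across all genomes.

    When the matrix carries exact (satisfied, total) integer pairs the
    comparison is exact; otherwise float equality is used.
    """
    if isinstance(mcf, MCFMatrix) and mcf.pairs is not None:
        sat, tot = mcf.pairs
        return [
            c
            for c in sat.columns
            if sat[c].nunique() == 1 and tot[c].nunique() == 1
        ]
    df = _as_frame(mcf)
    if df.shape[0] < 1:
        raise InsufficientRows("matrix has no rows")
    return [c for c in df.columns if df[c].nunique() == 1]


def column_sd(mcf: MCFMatrix | pd.DataFrame) -> pd.Series:
    """Sample standard deviation (n-1 denominator) of each module column."""
    df = _as_frame(mcf)
    if df.shape[0] < 2:
        raise InsufficientRows("need at least 2 rows for a standard deviation")
    return df.std(axis=0, ddof=1)


def group_mean_mcf(
    mcf: MCFMatrix | pd.DataFrame, factor: Mapping[str, str]
) -> pd.DataFrame:
    """Mean completeness per factor group (rows) and module (columns).

    Row order is the first-appearance order of the groups.
    """
    df = _as_frame(mcf)
    groups = _check_factor(df.index, factor)
    means = df.groupby(groups, sort=False).mean()
    means.index.name = "group"
    return means


def pca_scores(
    mcf: MCFMatrix | pd.DataFrame,
    n_components: int | None = None,
    scale: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of the genomes.

    Columns are centred; by default they are not scaled to unit variance
    since completeness fractions share the [0, 1] unit (``scale=True``
    standardizes, skipping zero-variance columns).  Returns the score
    matrix and the per-component explained-variance ratios.
    """
    df = _as_frame(mcf)
    x = df.to_numpy(dtype=float)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    max_comp = min(x.shape)
    k = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(x)
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=df.index, columns=cols),
        pca.explained_variance_ratio_,
    )


@dataclass
class ReportResult:
    """Paths and summary of an automated analysis report."""

    outdir: Path
    summary: dict
    figures: list[Path]


def build_report(
    mcf: MCFMatrix | pd.DataFrame,
    factors: Mapping[str, Mapping[str, str]] | None = None,
    outdir: str | Path = "report",
    *,
    n_components: int | None = None,
    scale: bool = False,
    fig_format: str = "png",
    dpi: int = 150,
) -> ReportResult:
    """Run the automated analysis suite on a completeness matrix.

    Always produced: genome/module counts, the global heatmap, the
    per-module boxplot, the per-module standard-deviation scatter and the
    zero-variance module table.  For every named factor additionally: the
    group-mean heatmap, a principal-component decomposition with its
    cumulative-variance plot, the component plot overlaid by group, and
    the within-group mean Euclidean distances.  Failed sections are
    recorded in the summary instead of aborting the report.
    """
    from . import plots  # deferred: keeps matplotlib out of pure analyses

    df = _as_frame(mcf)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    factors = dict(factors or {})
    figures: list[Path] = []
    summary: dict = {
        "schema_version": 1,
        "n_genomes": int(df.shape[0]),
        "n_modules": int(df.shape[1]),
        "factors": sorted(factors),
        "sections": {},
        "errors": {},
    }

    def section(name: str, fn):
        try:
            result = fn()
            summary["sections"][name] = True
            return result
        except Exception as exc:  # report survives a failed section
            summary["sections"][name] = False
            summary["errors"][name] = f"{type(exc).__name__}: {exc}"
            return None

    def figpath(stem: str) -> Path:
        p = outdir / f"{stem}.{fig_format}"
        figures.append(p)
        return p

    section("heatmap", lambda: plots.plot_heatmap(mcf, figpath("heatmap"), dpi=dpi))
    section(
        "boxplot",
        lambda: plots.plot_variance_boxplot(mcf, figpath("module_boxplot"), dpi=dpi),
    )

    def sd_section():
        sd = column_sd(df)
        plots.plot_scatter(sd, figpath("module_sd_scatter"), ylabel="SD of mcf", dpi=dpi)
        sd.rename("sd").to_csv(outdir / "module_sd.tsv", sep="\t", index_label="module")

    section("sd_scatter", sd_section)

    def zv_section():
        zv = zero_variance_modules(mcf)
        pd.DataFrame(
            {"module": zv, "mcf": [df[c].iloc[0] for c in zv]}
        ).to_csv(outdir / "zero_variance_modules.tsv", sep="\t", index=False)
        summary["zero_variance_modules"] = zv

    section("zero_variance", zv_section)

    if factors:
        scores, var_ratio = section(
            "pca", lambda: pca_scores(df, n_components=n_components, scale=scale)
        ) or (None, None)
        if scores is not None:
            section(
                "pca_cumulative_variance",
                lambda: plots.plot_scatter(
                    pd.Series(
                        np.cumsum(var_ratio),
                        index=[f"PC{i+1}" for i in range(len(var_ratio))],
                    ),
                    figpath("pca_cumulative_variance"),
                    ylabel="cumulative explained variance",
                    dpi=dpi,
                ),
            )
        summary["group_mean_distance"] = {}
        for fname, factor in factors.items():
            section(
                f"group_mean_heatmap:{fname}",
                lambda f=factor: plots.plot_heatmap(
                    group_mean_mcf(df, f),
                    figpath(f"group_mean_heatmap_{fname}"),
                    dpi=dpi,
                ),
            )
            if scores is not None:
                section(
                    f"pc_plot:{fname}",
                    lambda f=factor: plots.plot_scatter_by_factors(
                        scores.iloc[:, : min(2, scores.shape[1])],
                        f,
                        figpath(f"pc_plot_{fname}"),
                        dpi=dpi,
                    ),
                )

                def dist_section(f=factor, name=fname):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", SingletonGroupWarning)
                        dists = grouped_mean_distance(scores, f)
                    summary["group_mean_distance"][name] = {
                        g: (None if np.isnan(v) else v) for g, v in dists.items()
                    }
                    pd.Series(dists, name="mean_euclidean_distance").to_csv(
                        outdir / f"group_mean_distance_{name}.tsv",
                        sep="\t",
                        index_label="group",
                    )

                section(f"group_distance:{fname}", dist_section)
    else:
        summary["skipped"] = (
            "no factors supplied: group heatmap, principal-component plots "
            "and grouped distances skipped"
        )

    summary["figures"] = [p.name for p in figures if p.exists()]
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    _write_report_md(outdir, summary)
    return ReportResult(outdir, summary, [p for p in figures if p.exists()])


def _write_report_md(outdir: Path, summary: dict) -> None:
    lines = [
        "# Module completeness report",
        "",
        f"- genomes analysed: {summary['n_genomes']}",
        f"- modules analysed: {summary['n_modules']}",
        f"- zero-variance modules: "
        f"{', '.join(summary.get('zero_variance_modules', [])) or 'none'}",
        "",
    ]
    if summary.get("skipped"):
        lines.append(f"_{summary['skipped']}_")
    for fname, dists in summary.get("group_mean_distance", {}).items():
        lines.append(f"## Within-group spread by {fname}")
        lines.append("")
        lines.append("| group | mean Euclidean distance |")
        lines.append("| --- | --- |")
        for g, v in dists.items():
            lines.append(f"| {g} | {'undefined' if v is None else f'{v:.4f}'} |")
        lines.append("")
    if summary["figures"]:
        lines.append("## Figures")
        lines.append("")
        for f in summary["figures"]:
            lines.append(f"- {f}")
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
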