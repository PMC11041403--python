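"""Plotting: log-heat heatmaps (optionally with dendrogram margins),
2-D embedding scatters, and R^2-over-time line graphs."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram

from .cooccurrence import AxisOrdering, log_heat
from .errors import ConfigurationError
from .forecast import ForecastRun

__all__ = ["plot_heatmap", "plot_r2_trace", "plot_embedding_scatter"]


def _save(fig, out: str | Path, svg: bool = True) -> list[Path]:
    out = Path(out)
    paths = [out.with_suffix(".png")]
    fig.savefig(paths[0], dpi=150, bbox_inches="tight")
    if svg:
        paths.append(out.with_suffix(".svg"))
        fig.savefig(paths[1], bbox_inches="tight")
    plt.close(fig)
    return paths


def plot_heatmap(
    matrix: np.ndarray,
    ordering: AxisOrdering,
    out: str | Path,
    scale: str = "log",
    with_dendrograms: bool = False,
    title: str = "",
) -> list[Path]:
    """Heatmap with AI keywords on rows and BIO keywords on columns.

    ``scale='log'`` applies log10(1+x).  Matrices containing negative values
    (difference heatmaps) get a diverging palette centred at zero.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.size == 0:
        raise ConfigurationError("cannot plot an empty matrix")
    diverging = bool(np.any(matrix < 0))
    data = matrix if (diverging or scale == "linear") else log_heat(matrix)

    if with_dendrograms and ordering.ai_linkage is not None:
        fig = plt.figure(figsize=(11, 8))
        gs = fig.add_gridspec(2, 2, width_ratios=[1, 5], height_ratios=[1, 5], wspace=0.02, hspace=0.02)
        ax_top = fig.add_subplot(gs[0, 1])
        ax_left = fig.add_subplot(gs[1, 0])
        ax = fig.add_subplot(gs[1, 1])
        if ordering.bio_linkage is not None:
            dendrogram(ordering.bio_linkage, ax=ax_top, no_labels=True, color_threshold=0)
        dendrogram(ordering.ai_linkage, ax=ax_left, orientation="left", no_labels=True, color_threshold=0)
        ax_top.axis("off")
        ax_left.axis("off")
    else:
        fig, ax = plt.subplots(figsize=(9, 7))

    if diverging:
        vmax = float(np.max(np.abs(data))) or 1.0
        im = ax.imshow(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    else:
        im = ax.imshow(data, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(ordering.bio_order)))
    ax.set_xticklabels(ordering.bio_order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(ordering.ai_order)))
    ax.set_yticklabels(ordering.ai_order, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.7)
    if title:
        ax.set_title(title)
    return _save(fig, out)


def plot_r2_trace(runs: Sequence[ForecastRun], out: str | Path, labels=None) -> list[Path]:
    """One line per run: x = bin index, y = R^2.  Missing bins leave gaps."""
    runs = list(runs)
    if not runs or all(not r.r2_trace for r in runs):
        raise ConfigurationError("no run with a non-empty r2 trace")
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for k, run in enumerate(runs):
        if not run.r2_trace:
            continue
        bins = sorted(run.r2_trace)
        label = labels[k] if labels else f"{run.backend} w={run.window.w}"
        # break the line at gaps rather than interpolating across them
        xs, ys = [], []
        for b in range(bins[0], bins[-1] + 1):
            if b in run.r2_trace:
                xs.append(b)
                ys.append(run.r2_trace[b])
            else:
                xs.append(b)
                ys.append(np.nan)
        ax.plot(xs, ys, marker="o", label=label)
    ax.set_xlabel("time bin")
    ax.set_ylabel(r"$R^2$")
    ax.legend()
    return _save(fig, out)


def plot_embedding_scatter(
    coords: Mapping[str, tuple[float, float]], out: str | Path, title: str = ""
) -> list[Path]:
    fig, ax = plt.subplots(figsize=(7, 7))
    xs = [xy[0] for xy in coords.values()]
    ys = [xy[1] for xy in coords.values()]
    ax.scatter(xs, ys, s=12)
    for term, (x, y) in coords.items():
        ax.annotate(term, (x, y), fontsize=6)
    if title:
        ax.set_title(title)
    return _save(fig, out)
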