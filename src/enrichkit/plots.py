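"""Bar and bubble plots of enrichment results.

Bar plots show the top terms with bar length −log10(q); bubble plots show
fold enrichment (or gene ratio k/n) on x, terms on y, bubble area
proportional to the overlap count k, and color mapped to q on a reversed
scale so the most significant terms are darkest.  Output is deterministic:
rendering the same table twice yields byte-identical vector files (embedded
timestamps are suppressed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless; must precede pyplot import
matplotlib.rcParams["svg.hashsalt"] = "enrichkit"  # deterministic SVG ids
import matplotlib.pyplot as plt
import numpy as np

from .enrich import EnrichmentTable
from .errors import ValidationError

#: q-values are floored here before −log10 so q = 0 still plots finitely
Q_FLOOR = 1e-300
LOG_Q_CAP = 300.0
_NAME_LIMIT = 60


@dataclass
class PlotSpec:
    """Rendering options shared by both figure types."""

    top_n: int = 20
    rank_by: str = "q_value"  # or "p_value"
    category_facet: bool = False
    output_format: str = "png"  # png, svg or pdf
    x_axis: str = "fold_enrichment"  # bubble plots: or "gene_ratio"

    def __post_init__(self):
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        if self.rank_by not in ("q_value", "p_value"):
            raise ValidationError("rank_by must be 'q_value' or 'p_value'")
        if self.output_format not in ("png", "svg", "pdf"):
            raise ValidationError("output_format must be png, svg or pdf")
        if self.x_axis not in ("fold_enrichment", "gene_ratio"):
            raise ValidationError("x_axis must be 'fold_enrichment' or 'gene_ratio'")


def _truncate(name: str) -> str:
    if len(name) <= _NAME_LIMIT:
        return name
    return name[: _NAME_LIMIT - 1] + "…"


def _select_rows(table: EnrichmentTable, spec: PlotSpec):
    if not table.rows:
        raise ValidationError("cannot plot an empty enrichment table")
    key = (lambda r: (r.q_value, r.term_id)) if spec.rank_by == "q_value" else (
        lambda r: (r.p_value, r.term_id)
    )
    rows = sorted(table.rows, key=key)
    if spec.top_n < len(rows):
        rows = rows[: spec.top_n]
    else:
        if spec.top_n > len(rows):
            warnings.warn(
                f"top_n={spec.top_n} exceeds table size {len(rows)}; drawing all rows",
                stacklevel=3,
            )
    return rows


def _neglog_q(rows) -> np.ndarray:
    q = np.maximum(np.array([r.q_value for r in rows]), Q_FLOOR)
    return np.minimum(-np.log10(q), LOG_Q_CAP)


def _save(fig, path, spec: PlotSpec) -> None:
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower() or spec.output_format
    # strip volatile metadata so vector output is byte-stable
    metadata = {"Date": None} if fmt == "svg" else ({"CreationDate": None} if fmt == "pdf" else None)
    fig.savefig(path, format=fmt, metadata=metadata)
    plt.close(fig)


def bar_plot(table: EnrichmentTable, spec: PlotSpec, path) -> Path:
    """Horizontal bar plot of the top terms; bar length −log10(q)."""
    rows = _select_rows(table, spec)
    groups = [(None, rows)]
    if spec.category_facet:
        categories = sorted({r.category for r in rows})
        groups = [(c, [r for r in rows if r.category == c]) for c in categories]
    fig, axes = plt.subplots(
        len(groups), 1, figsize=(8, max(2.0, 0.4 * len(rows) + 1.2)), squeeze=False,
        constrained_layout=True,
    )
    for ax, (category, group) in zip(axes.ravel(), groups):
        heights = _neglog_q(group)
        labels = [_truncate(r.term_name or r.term_id) for r in group]
        y = np.arange(len(group))
        ax.barh(y, heights, color="#3b6ea5")
        ax.set_yticks(y)
        ax.set_yticklabels(labels, fontsize=8)
        ax.invert_yaxis()  # most significant on top
        ax.set_xlabel("-log10(q)")
        if category is not None:
            ax.set_title(category, fontsize=9)
    return _save(fig, path, spec) or Path(path)


def bubble_plot(table: EnrichmentTable, spec: PlotSpec, path) -> Path:
    """Bubble plot: x per ``spec.x_axis``, area ∝ k, color = q (reversed)."""
    rows = _select_rows(table, spec)
    if spec.x_axis == "gene_ratio":
        x = np.array([r.counts.k / r.counts.n for r in rows])
        xlabel = "gene ratio (k/n)"
    else:
        x = np.array([r.fold for r in rows])
        xlabel = "fold enrichment"
    k = np.array([r.counts.k for r in rows], dtype=float)
    q = np.maximum(np.array([r.q_value for r in rows]), Q_FLOOR)
    y = np.arange(len(rows))
    labels = [_truncate(r.term_name or r.term_id) for r in rows]
    fig, ax = plt.subplots(
        figsize=(8, max(2.0, 0.4 * len(rows) + 1.2)), constrained_layout=True
    )
    scatter = ax.scatter(
        x, y, s=20 + 12 * k, c=q, cmap="viridis_r", edgecolors="black", linewidths=0.4
    )
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=8)
    ax.invert_yaxis()
    ax.set_xlabel(xlabel)
    cbar = fig.colorbar(scatter, ax=ax)
    cbar.set_label("q-value")
    return _save(fig, path, spec) or Path(path)
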