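"""Dendrogram + heatmap rendering of clustering results.

One static figure per grouping: the agglomerative tree on the left, one
or two color bands (groups and, for two-tier results, subgroups), and the
value heatmap with rows in deterministic leaf order.  Missing entries are
drawn in a reserved color that appears in no value colormap.  A JSON
sidecar records the leaf order and band colors so figures can be checked
structurally without image parsing.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colormaps
from matplotlib.colors import to_hex
from scipy.cluster import hierarchy

from .cluster import Grouping
from .omics import OmicsInputError

__all__ = ["render_dendrogram_heatmap", "MISSING_COLOR"]

MISSING_COLOR = "#b0b0b0"  # reserved for missing entries only


def _band_colors(ids, cmap_name="tab10"):
    cmap = colormaps[cmap_name]
    uniq = sorted(set(ids))
    lut = {g: to_hex(cmap(i % cmap.N)) for i, g in enumerate(uniq)}
    return [lut[g] for g in ids], lut


def render_dendrogram_heatmap(
    grouping: Grouping,
    matrix: np.ndarray,
    out_path,
    row_labels=None,
    title: str = "",
) -> dict:
    """Render the grouping over ``matrix`` rows as SVG and PNG.

    ``matrix`` rows must correspond to the grouping's components (order
    given by ``row_labels``, default: grouping key order).  Returns a dict
    with the figure paths, the leaf order used, and the sidecar path.
    """
    if not grouping.groups:
        raise OmicsInputError("empty grouping")
    labels = list(row_labels) if row_labels is not None else list(grouping.groups)
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] != len(labels):
        raise OmicsInputError(
            f"matrix has {X.shape[0]} rows for {len(labels)} components"
        )
    if grouping.tree is not None and set(grouping.tree.labels) == set(labels):
        leaf_order = grouping.tree.leaf_order
    else:
        leaf_order = sorted(labels, key=lambda c: (grouping.groups.get(c, 0), c))
    idx = [labels.index(c) for c in leaf_order]
    Xo = X[idx]

    has_subgroups = bool(grouping.subgroups)
    n_bands = 2 if has_subgroups else 1
    fig_h = max(3.0, 0.22 * len(labels) + 1.5)
    fig, axes = plt.subplots(
        1,
        2 + n_bands,
        figsize=(9 + 0.15 * X.shape[1], fig_h),
        gridspec_kw={"width_ratios": [2] + [0.25] * n_bands + [6]},
    )
    ax_tree, ax_bands, ax_heat = axes[0], axes[1:-1], axes[-1]

    if grouping.tree is not None and set(grouping.tree.labels) == set(labels):
        hierarchy.dendrogram(
            grouping.tree.Z,
            orientation="left",
            no_labels=True,
            ax=ax_tree,
            color_threshold=0,
            above_threshold_color="0.3",
        )
    ax_tree.set_axis_off()

    group_ids = [grouping.groups[c] for c in leaf_order]
    band_specs = [("group", group_ids)]
    if has_subgroups:
        band_specs.append(
            ("subgroup", [
                (grouping.groups[c], grouping.subgroups.get(c, 1))
                for c in leaf_order
            ])
        )
    sidecar_bands = {}
    for ax, (name, ids) in zip(ax_bands, band_specs):
        colors, lut = _band_colors(ids)
        for i, color in enumerate(colors):
            ax.axhspan(i, i + 1, color=color)
        ax.set_ylim(0, len(colors))
        ax.invert_yaxis()
        ax.set_axis_off()
        ax.set_title(name, fontsize=7)
        sidecar_bands[name] = {str(k): v for k, v in lut.items()}

    cmap = colormaps["viridis"].copy()
    cmap.set_bad(MISSING_COLOR)
    masked = np.ma.masked_invalid(Xo)
    im = ax_heat.pcolormesh(masked, cmap=cmap)
    ax_heat.set_ylim(0, len(leaf_order))
    ax_heat.invert_yaxis()
    ax_heat.set_yticks(np.arange(len(leaf_order)) + 0.5)
    ax_heat.set_yticklabels(leaf_order, fontsize=6)
    ax_heat.yaxis.tick_right()
    ax_heat.set_xticks([])
    fig.colorbar(im, ax=ax_heat, shrink=0.6)
    if title:
        fig.suptitle(title)
    fig.tight_layout()

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    svg = out_path.with_suffix(".svg")
    png = out_path.with_suffix(".png")
    fig.savefig(svg)
    fig.savefig(png, dpi=120)
    plt.close(fig)

    sidecar = out_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "leaf_order": leaf_order,
                "bands": sidecar_bands,
                "missing_color": MISSING_COLOR,
                "has_missing": bool(np.isnan(X).any()),
            },
            indent=2,
            sort_keys=True,
        )
    )
    return {"svg": svg, "png": png, "sidecar": sidecar, "leaf_order": leaf_order}
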