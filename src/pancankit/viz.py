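"""Figure rendering for analysis payloads.

Every statistical number shown on a figure (stars, r values, HR text,
log-rank p) is read from the analysis payload; nothing is recomputed
here.  Rendering writes a static file plus a ``render_manifest.yaml``
sidecar recording the plot kind, the layout seed and a hash of the
payload, so a figure can be traced back to its numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import stats

PLOT_KINDS = ("box", "paired_box", "pan_box", "radar", "heatmap",
              "triangle_heatmap", "forest", "km", "roc", "scatter",
              "network", "gsea_running_sum")

# approximations of the journal-style categorical palettes
PALETTES = {
    "jco": ["#0073C2", "#EFC000", "#868686", "#CD534C", "#7AA6DC", "#003C67"],
    "npg": ["#E64B35", "#4DBBD5", "#00A087", "#3C5488", "#F39B7F", "#8491B4"],
    "default": ["#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd"],
}


@dataclass
class PlotSpec:
    kind: str
    payload: dict
    title: str = ""
    palette: str = "jco"
    legend: str = "right"
    lowcol: str = "blue"
    highcol: str = "red"

    def __post_init__(self):
        if self.kind not in PLOT_KINDS:
            raise ValueError(f"unknown plot kind {self.kind!r}; "
                             f"one of {PLOT_KINDS}")


_REQUIRED = {
    "box": ("groups",), "paired_box": ("groups",), "pan_box": ("table",),
    "radar": ("table",), "heatmap": ("r",), "triangle_heatmap": ("r",),
    "forest": ("table",), "km": ("curves", "p"), "roc": ("roc",),
    "scatter": ("x", "y"), "network": ("edges", "genes", "terms"),
    "gsea_running_sum": ("table",),
}


def star_annotations(table) -> list:
    """Per-row significance stars for any table carrying a p column."""
    if isinstance(table, stats.TestResult):
        return [stats.significance_stars(table.p)]
    if "p" not in table.columns:
        raise ValueError("payload table has no p column")
    return [stats.significance_stars(p) for p in table["p"]]


def _payload_hash(payload: dict) -> str:
    def default(obj):
        if isinstance(obj, pd.DataFrame):
            return obj.to_csv()
        if isinstance(obj, pd.Series):
            return obj.to_csv()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return float(obj)
        return repr(obj)
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def render(spec: PlotSpec, path, format: str | None = None,
           seed: int = 0) -> dict:
    """Render a plot spec to PDF/PNG/SVG and write the sidecar manifest."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower() or "pdf"
    if fmt not in ("pdf", "png", "svg"):
        raise ValueError(f"unsupported figure format {fmt!r}")
    missing = [f for f in _REQUIRED[spec.kind] if f not in spec.payload]
    if missing:
        raise ValueError(f"plot kind {spec.kind!r} payload lacks fields {missing}")
    payload_hash = _payload_hash(spec.payload)

    fig = _DISPATCH[spec.kind](spec, seed)
    fig.suptitle(spec.title or spec.kind)
    fig.savefig(path, format=fmt, dpi=300)
    plt.close(fig)

    record = {"path": str(path), "kind": spec.kind, "format": fmt,
              "seed": seed, "payload_hash": payload_hash,
              "axes": _axis_count(spec)}
    manifest = path.with_name(path.stem + ".render_manifest.yaml")
    manifest.write_text(yaml.safe_dump(record))
    return record


def _axis_count(spec: PlotSpec) -> int:
    if spec.kind == "radar":
        return len(spec.payload["table"])
    if spec.kind == "forest":
        return len(spec.payload["table"])
    return 1


def _colors(spec: PlotSpec, n: int) -> list:
    pal = PALETTES.get(spec.palette, PALETTES["default"])
    return [pal[i % len(pal)] for i in range(n)]


def _fig(width=6.0, height=4.0):
    return plt.subplots(figsize=(width, height))


def _render_box(spec: PlotSpec, seed: int):
    groups = spec.payload["groups"]
    fig, ax = _fig()
    labels = list(groups)
    data = [np.asarray(groups[k]) for k in labels]
    box = ax.boxplot(data, tick_labels=labels, patch_artist=True)
    for patch, color in zip(box["boxes"], _colors(spec, len(labels))):
        patch.set_facecolor(color)
    stars = spec.payload.get("stars")
    if stars:
        top = max(v.max() for v in data if len(v))
        ax.text(0.5 * (1 + len(labels)), top * 1.02, stars, ha="center")
    ax.set_ylabel(spec.payload.get("ylabel", "log2(TPM+1)"))
    return fig


def _render_paired_box(spec: PlotSpec, seed: int):
    fig = _render_box(spec, seed)
    ax = fig.axes[0]
    groups = spec.payload["groups"]
    data = [np.asarray(v) for v in groups.values()]
    if len(data) == 2 and len(data[0]) == len(data[1]):
        for a, b in zip(data[0], data[1]):
            ax.plot([1, 2], [a, b], color="grey", lw=0.4, alpha=0.5)
    return fig


def _render_pan_box(spec: PlotSpec, seed: int):
    table = spec.payload["table"]
    fig, ax = _fig(max(6.0, 0.4 * len(table)), 4.0)
    x = np.arange(len(table))
    ax.bar(x, table["effect"], color=_colors(spec, len(table)))
    ax.set_xticks(x)
    ax.set_xticklabels(table.index, rotation=90, fontsize=7)
    if "stars" in table.columns:
        for xi, (eff, s) in enumerate(zip(table["effect"], table["stars"])):
            ax.text(xi, eff, s, ha="center", va="bottom", fontsize=6)
    ax.set_ylabel("effect")
    return fig


def _render_radar(spec: PlotSpec, seed: int):
    table = spec.payload["table"]
    n = len(table)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    values = table["effect"].to_numpy(dtype=float)
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(111, polar=True)
    ax.plot(np.r_[angles, angles[:1]], np.r_[values, values[:1]],
            color=_colors(spec, 1)[0])
    ax.fill(np.r_[angles, angles[:1]], np.r_[values, values[:1]], alpha=0.25)
    labels = [f"{c}{s}" for c, s in zip(
        table.index, table.get("stars", [""] * n))]
    ax.set_xticks(angles)
    ax.set_xticklabels(labels, fontsize=7)
    return fig


def _diverging_cmap(spec: PlotSpec):
    from matplotlib.colors import LinearSegmentedColormap, TwoSlopeNorm
    cmap = LinearSegmentedColormap.from_list(
        "user", [spec.lowcol, "white", spec.highcol])
    return cmap, TwoSlopeNorm(vmin=-1, vcenter=0.0, vmax=1)


def _render_heatmap(spec: PlotSpec, seed: int, mask_upper: bool = False):
    r = spec.payload["r"].astype(float)
    vals = r.to_numpy()
    if mask_upper:
        vals = np.where(np.triu(np.ones_like(vals, dtype=bool), k=1),
                        np.nan, vals)
    fig, ax = _fig(max(4.0, 0.35 * r.shape[1]), max(3.0, 0.3 * r.shape[0]))
    cmap, norm = _diverging_cmap(spec)
    im = ax.imshow(vals, cmap=cmap, norm=norm, aspect="auto")
    ax.set_xticks(range(r.shape[1]))
    ax.set_xticklabels(r.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(r.shape[0]))
    ax.set_yticklabels(r.index, fontsize=6)
    stars = spec.payload.get("stars")
    if stars is not None:
        for i in range(r.shape[0]):
            for j in range(r.shape[1]):
                if not np.isnan(vals[i, j]) and stars.iloc[i, j]:
                    ax.text(j, i, stars.iloc[i, j], ha="center", va="center",
                            fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.7)
    return fig


def _render_triangle(spec: PlotSpec, seed: int):
    return _render_heatmap(spec, seed, mask_upper=True)


def _render_forest(spec: PlotSpec, seed: int):
    table = spec.payload["table"]
    fig, ax = _fig(6.0, max(3.0, 0.3 * len(table)))
    y = np.arange(len(table))[::-1]
    ax.errorbar(table["hr"], y,
                xerr=[table["hr"] - table["ci_low"],
                      table["ci_high"] - table["hr"]],
                fmt="s", color="black", ecolor="grey", capsize=2)
    ax.axvline(1.0, color="red", lw=0.8, ls="--")
    ax.set_yticks(y)
    labels = [f"{c}  HR={row.hr:.2f} [{row.ci_low:.2f}, {row.ci_high:.2f}]"
              for c, row in zip(table.index, table.itertuples())]
    ax.set_yticklabels(labels, fontsize=7)
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio (per SD)")
    return fig


def _render_km(spec: PlotSpec, seed: int):
    curves = spec.payload["curves"]
    fig, ax = _fig()
    for (label, curve), color in zip(curves.items(), _colors(spec, len(curves))):
        t = np.r_[0.0, np.repeat(curve.times, 2)]
        s = np.r_[1.0, 1.0, np.repeat(curve.survival, 2)[:-1]]
        ax.plot(t, s, label=label, color=color)
    ax.set_ylim(0, 1.05)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.legend(loc="best")
    ax.text(0.6, 0.9, f"log-rank p = {spec.payload['p']:.3g}",
            transform=ax.transAxes, fontsize=8)
    return fig


def _render_roc(spec: PlotSpec, seed: int):
    roc = spec.payload["roc"]
    fig, ax = _fig(4.5, 4.5)
    ax.plot(roc.fpr, roc.tpr, color=_colors(spec, 1)[0])
    ax.plot([0, 1], [0, 1], color="grey", ls="--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.text(0.55, 0.1, f"AUC = {roc.auc:.3f}", fontsize=9)
    return fig


def _render_scatter(spec: PlotSpec, seed: int):
    x = np.asarray(spec.payload["x"], dtype=float)
    y = np.asarray(spec.payload["y"], dtype=float)
    fig, ax = _fig(4.5, 4.0)
    if spec.payload.get("density"):
        ax.hexbin(x, y, gridsize=30, cmap="Blues")
    else:
        ax.scatter(x, y, s=8, alpha=0.6, color=_colors(spec, 1)[0])
    if "slope" in spec.payload:
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, spec.payload["slope"] * xs + spec.payload["intercept"],
                color="red", lw=1)
    if "r" in spec.payload:
        ax.text(0.05, 0.95,
                f"r = {spec.payload['r']:.3f}, p = {spec.payload['p']:.2g}",
                transform=ax.transAxes, va="top", fontsize=8)
    ax.set_xlabel(spec.payload.get("xlabel", "x"))
    ax.set_ylabel(spec.payload.get("ylabel", "y"))
    return fig


def _render_network(spec: PlotSpec, seed: int):
    import networkx as nx
    g = nx.Graph()
    genes = spec.payload["genes"]
    terms = [t for t, _ in spec.payload["terms"]]
    g.add_nodes_from(genes)
    g.add_nodes_from(terms)
    g.add_edges_from(spec.payload["edges"])
    fig, ax = _fig(6.0, 6.0)
    pos = nx.spring_layout(g, seed=seed)  # layout fixed by the render seed
    nx.draw_networkx_nodes(g, pos, nodelist=genes, node_color="#CD534C",
                           node_size=180, ax=ax)
    nx.draw_networkx_nodes(g, pos, nodelist=terms, node_color="#0073C2",
                           node_size=320, ax=ax)
    nx.draw_networkx_edges(g, pos, ax=ax, alpha=0.5)
    nx.draw_networkx_labels(g, pos, font_size=6, ax=ax)
    ax.axis("off")
    return fig


def _render_gsea(spec: PlotSpec, seed: int):
    table = spec.payload["table"]
    fig, ax = _fig()
    top = table.nsmallest(min(5, len(table)), "p")
    ax.barh(np.arange(len(top)), top["nes"], color=_colors(spec, len(top)))
    ax.set_yticks(np.arange(len(top)))
    ax.set_yticklabels(top["set_name"], fontsize=7)
    ax.set_xlabel("normalized enrichment score")
    return fig


_DISPATCH = {
    "box": _render_box, "paired_box": _render_paired_box,
    "pan_box": _render_pan_box, "radar": _render_radar,
    "heatmap": _render_heatmap, "triangle_heatmap": _render_triangle,
    "forest": _render_forest, "km": _render_km, "roc": _render_roc,
    "scatter": _render_scatter, "network": _render_network,
    "gsea_running_sum": _render_gsea,
}
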