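"""PAM-pattern summaries: max-normalized heatmap, sequence logo, PAM wheel.

* The **heatmap** arranges the 256 PAM efficiencies on a 16×16 grid (rows =
  bases 1–2, columns = bases 3–4, A,C,G,T lexicographic order) normalized to
  the highest efficiency, so the best PAM is exactly 1.
* The **sequence logo** summarizes a weighted PAM set as per-position base
  frequencies and Shannon information content IC_i = 2 + Σ_b f log2 f bits;
  letter heights are f·IC.  Logos are enrichment-factor weighted by default.
* The **PAM wheel** is a prefix tree drawn as concentric rings (position 1
  innermost): each node's angular span is proportional to the summed
  enrichment weight of its member PAMs, so the wheel shows how a base at one
  position conditions the composition of the next.

Figures are written as vector graphics and every matrix also as TSV, so all
plots are reproducible from the tabular outputs alone.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "besskit"  # deterministic SVG ids

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .amplicon import DNA_BASES

__all__ = [
    "HeatmapMatrix",
    "LogoMatrix",
    "WheelNode",
    "heatmap_matrix",
    "logo_matrix",
    "pam_wheel_tree",
    "plot_heatmap",
    "plot_logo",
    "plot_wheel",
    "write_reports",
]

BASE_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


def _savefig(fig, path) -> None:
    # strip volatile timestamps so identical runs give identical bytes
    meta = {"Date": None} if str(path).endswith(".svg") else None
    fig.savefig(path, metadata=meta)
    plt.close(fig)


@dataclass
class HeatmapMatrix:
    """16×16 max-normalized efficiency grid with row/column dinucleotides."""

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    norm_constant: float
    mask: np.ndarray  # True where the PAM was absent from the input

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)


@dataclass
class LogoMatrix:
    """Per-position base frequencies, information content and letter heights."""

    freqs: pd.DataFrame  # rows A,C,G,T; columns 1..k
    information: np.ndarray  # bits per position, in [0, 2]
    heights: pd.DataFrame  # freqs * information

    @property
    def k(self) -> int:
        return self.freqs.shape[1]


@dataclass
class WheelNode:
    """One arc of the PAM wheel: a PAM prefix with its angular span."""

    prefix: str
    weight: float
    theta0: float  # arc start, radians
    span: float  # arc width, radians
    children: dict[str, "WheelNode"] = field(default_factory=dict)

    def walk(self):
        yield self
        for b in sorted(self.children):
            yield from self.children[b].walk()


def heatmap_matrix(stats: pd.DataFrame, value_col: str = "efficiency") -> HeatmapMatrix:
    """Arrange per-PAM values on the 16×16 grid, normalized to the maximum.

    ``stats`` needs columns ``pam`` and ``value_col``; PAMs must be 4-mers.
    Missing PAMs are 0 with the mask flag set.  When every value is zero or
    undefined the matrix is all zeros (with a warning in the norm constant).
    """
    dinucs = [a + b for a in DNA_BASES for b in DNA_BASES]
    values = np.zeros((16, 16))
    mask = np.ones((16, 16), dtype=bool)
    row_of = {d: i for i, d in enumerate(dinucs)}
    for pam, val in zip(stats["pam"], stats[value_col]):
        if len(pam) != 4:
            raise ValueError(f"heatmap requires 4-mer PAMs, got {pam!r}")
        if pd.isna(val):
            continue
        values[row_of[pam[:2]], row_of[pam[2:]]] = val
        mask[row_of[pam[:2]], row_of[pam[2:]]] = False
    vmax = values.max()
    if vmax > 0:
        values = values / vmax
    return HeatmapMatrix(values, dinucs, list(dinucs), float(vmax), mask)


def logo_matrix(
    pams, weights: dict[str, float] | None = None
) -> LogoMatrix:
    """Weighted position frequency matrix and information content of a PAM set.

    With equal weights over the 16 NGGN sequences the information content is
    (0, 2, 2, 0) bits — the canonical-PAM signature.
    """
    pams = sorted(set(pams))
    if not pams:
        raise ValueError("PAM set must be non-empty")
    k = len(pams[0])
    if any(len(p) != k for p in pams):
        raise ValueError("all PAMs must have equal length")
    w = np.array(
        [1.0 if weights is None else float(weights.get(p, 0.0)) for p in pams]
    )
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights must not be all zero")
    freqs = np.zeros((4, k))
    base_row = {b: i for i, b in enumerate(DNA_BASES)}
    for p, wp in zip(pams, w):
        for i, b in enumerate(p):
            freqs[base_row[b], i] += wp
    freqs /= w.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    ic = np.clip(ic, 0.0, 2.0)
    cols = list(range(1, k + 1))
    fdf = pd.DataFrame(freqs, index=list(DNA_BASES), columns=cols)
    return LogoMatrix(fdf, ic, fdf * ic)


def pam_wheel_tree(ef: dict[str, float]) -> WheelNode:
    """Prefix tree of PAMs with arcs proportional to enrichment weight.

    The root spans the full circle; each node's children subdivide its arc
    in proportion to their summed weights, children ordered A<C<G<T.  Zero-
    weight PAMs contribute no arc; an all-zero input is an error.
    """
    ks = {len(p) for p in ef}
    if len(ks) > 1:
        raise ValueError("all PAMs must have equal length")
    pos = {p: float(w) for p, w in ef.items() if w > 0}
    if any(w < 0 for w in ef.values()):
        raise ValueError("weights must be non-negative")
    if not pos:
        raise ValueError("need at least one positive weight")
    root = WheelNode("", sum(pos.values()), 0.0, 2 * math.pi)

    def build(node: WheelNode, members: dict[str, float]) -> None:
        depth = len(node.prefix)
        if all(len(p) == depth for p in members):
            return
        theta = node.theta0
        for b in DNA_BASES:
            sub = {p: w for p, w in members.items() if p[depth] == b}
            if not sub:
                continue
            w = sum(sub.values())
            span = node.span * w / node.weight
            child = WheelNode(node.prefix + b, w, theta, span)
            node.children[b] = child
            theta += span
            build(child, sub)

    build(root, pos)
    return root


def wheel_frame(root: WheelNode) -> pd.DataFrame:
    rows = [
        {
            "prefix": n.prefix,
            "ring": len(n.prefix),
            "weight": n.weight,
            "theta0": n.theta0,
            "span": n.span,
        }
        for n in root.walk()
        if n.prefix
    ]
    return pd.DataFrame(rows, columns=["prefix", "ring", "weight", "theta0", "span"])


# ---------------------------------------------------------------------------
# plotting


def plot_heatmap(hm: HeatmapMatrix, path, title: str = "BE efficiency") -> None:
    fig, ax = plt.subplots(figsize=(7.2, 6.4))
    shown = np.ma.masked_where(hm.mask & (hm.values == 0), hm.values)
    im = ax.imshow(shown, cmap="viridis", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(16), hm.col_labels, rotation=90, fontsize=7)
    ax.set_yticks(range(16), hm.row_labels, fontsize=7)
    ax.set_xlabel("PAM bases 3-4")
    ax.set_ylabel("PAM bases 1-2")
    ax.set_title(f"{title} (max-normalized; max = {hm.norm_constant:.3g})")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    _savefig(fig, path)


def plot_logo(logo: LogoMatrix, path, title: str = "PAM sequence logo") -> None:
    """Stacked-letter logo: per column, letters scaled to f·IC bits."""
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    fp = FontProperties(family="DejaVu Sans", weight="bold")
    fig, ax = plt.subplots(figsize=(1.2 * logo.k + 1, 3.2))
    for ci, col in enumerate(logo.heights.columns):
        y = 0.0
        order = logo.heights[col].sort_values().index  # tallest on top
        for base in order:
            h = float(logo.heights.loc[base, col])
            if h <= 1e-9:
                continue
            tp = TextPath((0, 0), base, size=1.0, prop=fp)
            bb = tp.get_extents()
            tr = (
                Affine2D()
                .translate(-bb.x0, -bb.y0)
                .scale(0.9 / bb.width, h / bb.height)
                .translate(ci + 0.05, y)
            )
            ax.add_patch(
                PathPatch(tr.transform_path(tp), color=BASE_COLORS[base], lw=0)
            )
            y += h
    ax.set_xlim(-0.2, logo.k + 0.2)
    ax.set_ylim(0, 2.05)
    ax.set_xticks([i + 0.5 for i in range(logo.k)], [str(c) for c in logo.heights.columns])
    ax.set_xlabel("PAM position")
    ax.set_ylabel("bits")
    ax.set_title(title)
    fig.tight_layout()
    _savefig(fig, path)


def plot_wheel(root: WheelNode, path, title: str = "PAM wheel") -> None:
    """Concentric-ring wheel, position 1 innermost, arcs colored by base."""
    fig, ax = plt.subplots(figsize=(6.4, 6.4), subplot_kw={"projection": "polar"})
    depth_max = 0
    for node in root.walk():
        d = len(node.prefix)
        if d == 0:
            continue
        depth_max = max(depth_max, d)
        ax.bar(
            x=node.theta0 + node.span / 2,
            height=0.92,
            width=node.span,
            bottom=d - 0.5,
            color=BASE_COLORS[node.prefix[-1]],
            edgecolor="white",
            linewidth=0.4,
        )
    ax.set_ylim(0, depth_max + 0.6)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"{title} (ring = PAM position, innermost = 1)")
    handles = [plt.Rectangle((0, 0), 1, 1, color=BASE_COLORS[b]) for b in DNA_BASES]
    ax.legend(handles, DNA_BASES, loc="upper right", bbox_to_anchor=(1.15, 1.1))
    fig.tight_layout()
    _savefig(fig, path)


# ---------------------------------------------------------------------------
# report bundle


def write_reports(
    stats: pd.DataFrame,
    outdir,
    *,
    prefix: str = "bess",
    metadata: dict | None = None,
    figure_format: str = "svg",
) -> dict[str, str]:
    """Write the tabular and graphical summary bundle for one stats table.

    Produces the per-PAM stats TSV, heatmap matrix TSV + figure, logo
    matrix TSV + figure and wheel arcs TSV + figure (figures only where the
    inputs are defined), plus a run-metadata JSON with a checksum manifest.
    Returns the manifest mapping artifact name → path.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def save(name: str, fname: str):
        paths[name] = os.path.join(outdir, fname)
        return paths[name]

    stats.to_csv(save("stats_tsv", f"{prefix}_pam_stats.tsv"), sep="\t", index=False)

    if len(stats) and stats["pam"].str.len().eq(4).all():
        hm = heatmap_matrix(stats)
        hm.to_frame().to_csv(save("heatmap_tsv", f"{prefix}_heatmap.tsv"), sep="\t")
        plot_heatmap(hm, save("heatmap_fig", f"{prefix}_heatmap.{figure_format}"))

    functional = stats.loc[stats["functional"].astype(bool), "pam"].tolist()
    ef_weights = {
        p: float(v)
        for p, v in zip(stats["pam"], stats["enrichment_factor"])
        if not pd.isna(v) and v > 0
    }
    if functional:
        lw = {p: ef_weights.get(p, 0.0) for p in functional}
        logo = logo_matrix(functional, lw if sum(lw.values()) > 0 else None)
        ltab = logo.freqs.copy()
        ltab.loc["IC_bits"] = logo.information
        ltab.to_csv(save("logo_tsv", f"{prefix}_logo.tsv"), sep="\t")
        plot_logo(logo, save("logo_fig", f"{prefix}_logo.{figure_format}"),
                  title="Functional PAM logo (EF-weighted)")
    enriched_ef = {
        p: ef_weights[p]
        for p in stats.loc[stats["enriched"].astype(bool), "pam"]
        if p in ef_weights
    }
    if enriched_ef:
        root = pam_wheel_tree(enriched_ef)
        wheel_frame(root).to_csv(
            save("wheel_tsv", f"{prefix}_wheel.tsv"), sep="\t", index=False
        )
        plot_wheel(root, save("wheel_fig", f"{prefix}_wheel.{figure_format}"),
                   title="Enriched PAM wheel (EF-weighted)")

    meta = dict(metadata or {})
    meta.setdefault("thresholds", {
        k: stats.attrs[k]
        for k in ("functional_threshold", "enriched_threshold")
        if k in stats.attrs
    })
    meta["wheel_convention"] = "ring index = PAM position, position 1 innermost"
    meta["heatmap_convention"] = "rows = PAM bases 1-2, columns = bases 3-4, ACGT order"
    manifest = {}
    for name, p in paths.items():
        with open(p, "rb") as fh:
            manifest[name] = {
                "path": os.path.basename(p),
                "sha256": hashlib.sha256(fh.read()).hexdigest(),
            }
    meta["artifacts"] = manifest
    mpath = save("metadata_json", f"{prefix}_run_metadata.json")
    with open(mpath, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return paths
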