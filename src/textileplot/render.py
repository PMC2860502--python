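"""SVG rendering of textile plots.

One vertical axis per column at equal horizontal spacing; a circle per
genotype category whose area is proportional to the marginal count; a
ribbon (line) per adjacent genotype pair whose stroke width is
proportional to the pair count, capped at a maximum width with
proportionality preserved within the panel.  Larger coordinates point
upward.  Output is deterministic plain SVG 1.1 text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import AxisOrdering
from .genodata import GenotypeMatrix
from .solver import TextileLayout


@dataclass
class PlotSpec:
    """Visual constants of the rendering (all config-exposed)."""

    width: float = 800.0
    height: float = 500.0
    margin: float = 50.0
    circle_area_per_count: float = 0.12   # px^2 per individual
    ribbon_max_width: float = 14.0        # px cap for the widest ribbon
    axis_color: str = "#888888"
    circle_color: str = "#2b6ca3"
    ribbon_color: str = "#9bb7cc"
    highlight_color: str = "#d1495b"
    dendrogram: bool = False
    dendrogram_height: float = 80.0
    highlight_paths: list[list[str]] = field(default_factory=list)


def pair_counts(gm: GenotypeMatrix, order: list[int], j: int) -> np.ndarray:
    """c_j x c_{j+1} contingency table of genotype pairs between the
    display-adjacent axes at positions j and j+1 of *order*; individuals
    missing at either axis are excluded from this table only."""
    a, b = order[j], order[j + 1]
    ca = gm.axes[a].n_categories
    cb = gm.axes[b].n_categories
    tab = np.zeros((ca, cb), dtype=np.int64)
    ok = (gm.codes[:, a] >= 0) & (gm.codes[:, b] >= 0)
    np.add.at(tab, (gm.codes[ok, a], gm.codes[ok, b]), 1)
    return tab


def _fmt(x: float) -> str:
    return f"{x:.4f}".rstrip("0").rstrip(".")


def render_svg(layout: TextileLayout, gm: GenotypeMatrix,
               spec: PlotSpec | None = None,
               order: list[int] | None = None,
               ordering: AxisOrdering | None = None) -> str:
    """Render a solved layout to an SVG 1.1 document string."""
    spec = spec or PlotSpec()
    order = order if order is not None else (
        ordering.order if ordering is not None else list(range(layout.n_axes)))
    if not order:
        raise ValueError("empty layout")
    p = len(order)

    top = spec.margin + (spec.dendrogram_height if spec.dendrogram else 0.0)
    bottom = spec.height - spec.margin
    xs = (np.linspace(spec.margin, spec.width - spec.margin, p)
          if p > 1 else np.array([spec.width / 2.0]))

    coords = [layout.category_coords[a] for a in order]
    allv = np.concatenate(
        [v for v in coords if v is not None]
        + [layout.y[:, a][~np.isnan(layout.y[:, a])] for a in order
           if layout.category_coords[a] is None])
    lo, hi = float(allv.min()), float(allv.max())
    if hi == lo:
        hi = lo + 1.0

    def ypix(v: float) -> float:
        # larger coordinate values upward
        return bottom - (v - lo) / (hi - lo) * (bottom - top)

    parts = ['<?xml version="1.0" encoding="UTF-8"?>',
             f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
             f'width="{_fmt(spec.width)}" height="{_fmt(spec.height)}">']

    # dendrogram strip (above the axes)
    if spec.dendrogram and ordering is not None and ordering.merges:
        posx = {a: xs[k] for k, a in enumerate(order)}
        hmax = max(h for _, _, h in ordering.merges if np.isfinite(h)) or 1.0
        ytop, ybase = spec.margin, top

        def hpix(h: float) -> float:
            return ybase - min(h / hmax, 1.0) * (ybase - ytop)

        node_x: dict[frozenset, float] = {}
        node_y: dict[frozenset, float] = {}
        for left, right, h in ordering.merges:
            for grp in (left, right):
                if grp not in node_x:
                    gx = [posx[a] for a in grp if a in posx]
                    node_x[grp] = float(np.mean(gx))
                    node_y[grp] = ybase
            yh = hpix(h)
            x1, x2 = node_x[left], node_x[right]
            for x0, y0 in ((x1, node_y[left]), (x2, node_y[right])):
                parts.append(f'<line class="dendro" x1="{_fmt(x0)}" y1="{_fmt(y0)}" '
                             f'x2="{_fmt(x0)}" y2="{_fmt(yh)}" '
                             f'stroke="{spec.axis_color}" stroke-width="1"/>')
            parts.append(f'<line class="dendro" x1="{_fmt(x1)}" y1="{_fmt(yh)}" '
                         f'x2="{_fmt(x2)}" y2="{_fmt(yh)}" '
                         f'stroke="{spec.axis_color}" stroke-width="1"/>')
            merged = left | right
            node_x[merged] = (x1 + x2) / 2.0
            node_y[merged] = yh

    # axes
    for k, a in enumerate(order):
        parts.append(f'<line class="axis" x1="{_fmt(xs[k])}" y1="{_fmt(top)}" '
                     f'x2="{_fmt(xs[k])}" y2="{_fmt(bottom)}" '
                     f'stroke="{spec.axis_color}" stroke-width="1"/>')

    # ribbons between adjacent axes: width proportional to pair count,
    # capped; thickest drawn first so thin ribbons stay visible
    highlights = {tuple(hp) for hp in map(tuple, spec.highlight_paths)}
    for k in range(p - 1):
        a, b = order[k], order[k + 1]
        va, vb = layout.category_coords[a], layout.category_coords[b]
        if va is None or vb is None:
            continue  # quantitative axes carry no category ribbons
        tab = pair_counts(gm, order, k)
        mx = int(tab.max())
        if mx == 0:
            continue
        per_count = min(spec.ribbon_max_width / mx, 0.25)
        cells = [(int(tab[s, t]), s, t)
                 for s in range(tab.shape[0]) for t in range(tab.shape[1])
                 if tab[s, t] > 0]
        cells.sort(key=lambda c: (-c[0], c[1], c[2]))
        for cnt, s, t in cells:
            la = gm.axes[a].labels[s]
            lb = gm.axes[b].labels[t]
            hl = any(len(hp) > max(k + 1, 1) and hp[k] == la and hp[k + 1] == lb
                     for hp in highlights)
            color = spec.highlight_color if hl else spec.ribbon_color
            parts.append(
                f'<line class="ribbon" data-count="{cnt}" '
                f'x1="{_fmt(xs[k])}" y1="{_fmt(ypix(va[s]))}" '
                f'x2="{_fmt(xs[k + 1])}" y2="{_fmt(ypix(vb[t]))}" '
                f'stroke="{color}" stroke-width="{float(cnt * per_count)!r}"/>')

    # category circles: area proportional to marginal count
    for k, a in enumerate(order):
        v = layout.category_coords[a]
        if v is None:
            continue
        counts = np.bincount(gm.codes[:, a][gm.codes[:, a] >= 0],
                             minlength=gm.axes[a].n_categories)
        for s, cnt in enumerate(counts):
            if cnt == 0:
                continue  # zero-count category: no circle
            r = float(np.sqrt(cnt * spec.circle_area_per_count / np.pi))
            parts.append(
                f'<circle class="genotype" data-count="{int(cnt)}" '
                f'data-label="{gm.axes[a].labels[s]}" '
                f'cx="{_fmt(xs[k])}" cy="{_fmt(ypix(v[s]))}" r="{r!r}" '
                f'fill="{spec.circle_color}"/>')
    parts.append("</svg>")
    return "\n".join(parts)
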