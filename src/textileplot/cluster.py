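"""Axis reordering by similarity of solved coordinates.

The distance between two axes is the weighted mean absolute deviation of
the individual coordinates, averaged over individuals observed at both.
Ordering uses the ordered single end-linkage algorithm: seed a chain
with the closest pair, then repeatedly append the unplaced axis nearest
to either end of the chain.  The merge sequence doubles as a (caterpillar)
dendrogram.  Phenotype axes are excluded from clustering and kept
leftmost in the resulting display order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import TextileLayout


def axis_distance(layout: TextileLayout, j: int, k: int) -> float:
    """Weighted mean |y_ij - y_ik| over individuals observed at both axes.

    Returns NaN when no individual is observed at both."""
    w = layout.weights[:, j] * layout.weights[:, k]
    nw = w.sum()
    if nw == 0:
        return float("nan")
    diff = np.abs(np.nan_to_num(layout.y[:, j]) - np.nan_to_num(layout.y[:, k]))
    return float((w * diff).sum() / nw)


def distance_matrix(layout: TextileLayout, cols: list[int] | None = None
                    ) -> np.ndarray:
    cols = cols if cols is not None else list(range(layout.n_axes))
    p = len(cols)
    D = np.zeros((p, p))
    for a in range(p):
        for b in range(a + 1, p):
            D[a, b] = D[b, a] = axis_distance(layout, cols[a], cols[b])
    return D


@dataclass
class AxisOrdering:
    """Reordered axes with the merge tree of the chain construction."""

    order: list[int]                       # permutation of axis indices
    merges: list[tuple[frozenset, frozenset, float]]  # (left, right, height)
    distances: np.ndarray

    def newick(self, names: list[str] | None = None) -> str:
        """Newick string; branch lengths carry raw merge distances."""
        names = names or [f"axis{j + 1}" for j in range(len(self.order))]
        label: dict[frozenset, str] = {}
        height: dict[frozenset, float] = {}
        for j in self.order:
            s = frozenset([j])
            label[s] = names[j]
            height[s] = 0.0
        tree = None
        for left, right, h in self.merges:
            bl = max(h - height[left], 0.0)
            br = max(h - height[right], 0.0)
            merged = left | right
            label[merged] = f"({label[left]}:{bl:g},{label[right]}:{br:g})"
            height[merged] = h
            tree = merged
        if tree is None:
            return f"{names[self.order[0]]};" if self.order else ";"
        return label[tree] + ";"


def order_axes(D: np.ndarray, anchor: list[int] | None = None) -> AxisOrdering:
    """Ordered single end-linkage over a symmetric distance matrix.

    ``anchor`` is the initial (e.g. physical) order used for
    deterministic tie-breaking; missing distances (NaN) are treated as
    +inf.  Raises when every distance is missing.
    """
    D = np.asarray(D, dtype=float)
    p = D.shape[0]
    anchor = anchor if anchor is not None else list(range(p))
    rank = {j: r for r, j in enumerate(anchor)}
    Df = np.where(np.isnan(D), np.inf, D)
    np.fill_diagonal(Df, np.inf)
    if p == 1:
        return AxisOrdering([anchor[0]], [], D)
    if not np.isfinite(Df).any():
        raise ValueError("all pairwise distances are missing")

    # seed: closest pair, ties by anchor order
    best = None
    for a in range(p):
        for b in range(a + 1, p):
            key = (Df[a, b], min(rank[a], rank[b]), max(rank[a], rank[b]))
            if best is None or key < best[0]:
                best = (key, a, b)
    _, a, b = best
    if rank[a] > rank[b]:
        a, b = b, a
    chain = [a, b]
    merges = [(frozenset([a]), frozenset([b]), float(Df[a, b]))]
    unplaced = [j for j in anchor if j not in (a, b)]
    while unplaced:
        cand = None
        for u in unplaced:
            for end, side in ((chain[0], "left"), (chain[-1], "right")):
                key = (Df[end, u], rank[u], 0 if side == "right" else 1)
                if cand is None or key < cand[0]:
                    cand = (key, u, side)
        key, u, side = cand
        merges.append((frozenset(chain), frozenset([u]), float(key[0])))
        if side == "left":
            chain.insert(0, u)
        else:
            chain.append(u)
        unplaced.remove(u)
    return AxisOrdering(chain, merges, D)


def reorder(layout: TextileLayout, anchor: list[int] | None = None
            ) -> AxisOrdering:
    """Cluster-based display order for a solved layout.

    Phenotype axes are left out of the clustering and placed leftmost,
    ahead of the reordered SNP axes."""
    pheno = [j for j in range(layout.n_axes) if layout.axis_kinds[j] != "snp"]
    snps = [j for j in range(layout.n_axes) if layout.axis_kinds[j] == "snp"]
    D = distance_matrix(layout, snps)
    sub = order_axes(D, anchor=[snps.index(j) for j in (anchor or snps)
                                if j in snps])
    order = pheno + [snps[a] for a in sub.order]
    merges = [(frozenset(snps[x] for x in l), frozenset(snps[x] for x in r), h)
              for l, r, h in sub.merges]
    full = np.full((layout.n_axes, layout.n_axes), np.nan)
    for ia, a in enumerate(snps):
        for ib, b in enumerate(snps):
            full[a, b] = D[ia, ib]
    return AxisOrdering(order, merges, full)


def export_order_tsv(ordering: AxisOrdering, path,
                     names: list[str] | None = None) -> None:
    names = names or [f"axis{j + 1}" for j in range(len(ordering.order))]
    with open(path, "w") as fh:
        fh.write("display_position\taxis_index\taxis_id\n")
        for pos, j in enumerate(ordering.order):
            fh.write(f"{pos}\t{j}\t{names[j]}\n")
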