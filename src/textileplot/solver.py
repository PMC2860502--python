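"""Horizontalization layout solver.

Each axis j displays its categories at vertical coordinates
``v_j = alpha_j * 1 + B_j @ gamma_j`` (location + contrast-scaled scales);
individual i's polyline visits ``y_ij`` on every observed axis.  The
layout minimizes the weighted sum of squared deviations of each observed
coordinate from a per-individual horizontal level ``h_i``,

    Q = sum_j sum_i w_ij (y_ij - h_i)^2,

subject to fixing the total dispersion of the plot,

    sum_j sum_i w_ij (y_ij - ybar_j)^2 = n_eff,

with ``n_eff`` the total number of observed cells.  Both ``h_i`` and
``alpha_j`` are weighted means at the optimum, so they can be eliminated:
the residual of the two-way additive fit is linear in the stacked scale
vector ``gamma``, reducing the problem to minimizing a homogeneous
quadratic form ``gamma' M gamma`` under ``gamma' G gamma = n_eff`` with
``G`` block diagonal.  Whitening ``G`` turns this into an ordinary
symmetric eigenproblem whose smallest eigenvalue ``mu`` gives the
optimum ``Q = n_eff * mu``; the leading eigenvalue reported is
``lambda = 1 - mu``, which on complete data coincides with the leading
eigenvalue of the multiple-correspondence (homogeneity) eigenproblem.

Directions in the null space of ``G`` (empty categories, monomorphic
axes) move no observed point and are fixed at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .genodata import QUANTITATIVE, AxisEncoding

_RANK_TOL = 1e-10
_TIE_TOL = 1e-9


class DegenerateLayoutWarning(UserWarning):
    """The optimal layout is not unique (tied leading eigenvalues, e.g.
    when all axis pairs are empirically independent)."""


@dataclass
class TextileLayout:
    """Solved textile-plot geometry.

    Arrays are indexed over all n input individuals; individuals dropped
    from the fit (observed on fewer than two axes) have NaN rows in ``y``
    and ``h`` and False in ``kept``.
    """

    alpha: np.ndarray                 # (p,) axis locations
    gamma: list[np.ndarray]           # per axis, length c_j - 1 (quant: 1)
    category_coords: list[np.ndarray | None]  # per axis, length c_j; None for quant
    y: np.ndarray                     # (n, p) individual coordinates, NaN = missing
    h: np.ndarray                     # (n,) individual levels
    weights: np.ndarray               # (n, p) 0/1 observation weights (0 for dropped)
    codes: np.ndarray                 # (n, p) category codes, -1 missing/quant
    eigenvalue: float                 # leading eigenvalue lambda = 1 - mu_min
    objective: float                  # Q at the solution
    n_eff: float                      # total observed-cell count in the fit
    kept: np.ndarray                  # (n,) bool, individual in fit
    axis_kinds: list[str] = field(default_factory=list)
    category_labels: list[list[str]] = field(default_factory=list)
    degenerate: bool = False

    @property
    def n_axes(self) -> int:
        return self.y.shape[1]


def _axis_design(enc: AxisEncoding, kept: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observation weights, centered design Z_j, and centering offsets.

    Returns ``(w, Z, mu)`` with ``w`` the 0/1 weights restricted to kept
    individuals, ``Z`` the design whose weighted column means vanish and
    whose unobserved rows are zero, and ``mu`` such that the coordinate
    of category k is ``alpha_j + (B_j @ gamma_j)[k] - mu @ gamma_j``.
    """
    w = np.asarray(enc.weight, dtype=float) * kept
    nw = w.sum()
    if enc.kind == QUANTITATIVE:
        x = np.where(np.isnan(enc.raw), 0.0, enc.raw)
        mu = (w * x).sum() / nw if nw else 0.0
        xc = w * (x - mu)
        sd = np.sqrt((xc ** 2).sum() / nw) if nw else 0.0
        Z = (xc / sd)[:, None] if sd > 0 else np.zeros((len(w), 1))
        return w, Z, np.zeros(1)
    Z0 = enc.indicator @ enc.contrast         # rows are zero where missing
    mu = ((w[:, None] * Z0).sum(axis=0) / nw) if nw else np.zeros(Z0.shape[1])
    Z = np.where(w[:, None] > 0, Z0 - mu, 0.0)
    return w, Z, mu


def _solve_locations(W: np.ndarray, S: np.ndarray, m: np.ndarray,
                     pinvA: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal axis offsets and individual levels for residual field S."""
    WS = W * S
    rs = WS.sum(axis=1)
    b = -WS.sum(axis=0) + W.T @ (rs / m)
    alpha = pinvA @ b
    h = (rs + W @ alpha) / m
    return alpha, h


def solve_layout(axes: list[AxisEncoding],
                 phenotype_in_fit: bool = True) -> TextileLayout:
    """Global minimizer of the horizontalization criterion.

    Parameters
    ----------
    axes
        Encodings of every display axis, in display order (order does not
        affect the solution).
    phenotype_in_fit
        When False, phenotype axes are excluded from the objective and
        the dispersion constraint; they are then placed passively by
        unconstrained least-squares regression of the fitted levels on
        their own encoding.
    """
    p = len(axes)
    if p < 2:
        raise ValueError("need at least two axes")
    n = len(axes[0].weight)
    if n < 2:
        raise ValueError("need at least two individuals")
    in_fit = [phenotype_in_fit or enc.kind not in
              ("categorical_phenotype", QUANTITATIVE) for enc in axes]

    # drop individuals observed on < 2 fitted axes
    fit_cols = [j for j in range(p) if in_fit[j]]
    W_raw = np.column_stack([np.asarray(enc.weight, dtype=float) for enc in axes])
    m_fit = W_raw[:, fit_cols].sum(axis=1)
    kept = m_fit >= 2
    if not kept.all():
        warnings.warn(f"dropped {int((~kept).sum())} individual(s) "
                      "observed on fewer than two axes")
    designs = [_axis_design(enc, kept) for enc in axes]
    W = np.column_stack([w for w, _, _ in designs])
    Zs = [Z for _, Z, _ in designs]

    Wf = W[:, fit_cols]
    m = Wf.sum(axis=1)
    m_safe = np.where(m > 0, m, 1.0)
    n_eff = Wf.sum()

    # two-way additive elimination operator (p_fit x p_fit, singular along 1)
    ncol = Wf.sum(axis=0)
    A = np.diag(ncol) - Wf.T @ (Wf / m_safe[:, None])
    pinvA = np.linalg.pinv(A)

    # whitening of the block-diagonal constraint G_j = Z_j' Z_j
    transforms: list[np.ndarray] = []     # gamma_j = T_j @ theta_j
    blocks: list[tuple[int, int]] = []    # (axis index, whitened dim)
    for j in fit_cols:
        G = Zs[j].T @ Zs[j]
        if G.size == 0:
            transforms.append(np.zeros((0, 0)))
            blocks.append((j, 0))
            continue
        gvals, gvecs = np.linalg.eigh(G)
        keep = gvals > _RANK_TOL * max(gvals[-1], 1.0)
        T = gvecs[:, keep] / np.sqrt(gvals[keep])
        transforms.append(T)
        blocks.append((j, T.shape[1]))
    q = sum(r for _, r in blocks)
    if q == 0:
        raise ValueError("all axes are monomorphic: no layout exists")

    # whitened objective matrix via residual fields of unit directions
    R = np.empty((q, n, len(fit_cols)))
    k = 0
    for (j, r), T in zip(blocks, transforms):
        ZT = Zs[j] @ T
        for t in range(r):
            S = np.zeros((n, len(fit_cols)))
            S[:, fit_cols.index(j)] = ZT[:, t]
            a, h = _solve_locations(Wf, S, m_safe, pinvA)
            R[k + t] = Wf * (S + a[None, :] - h[:, None])
        k += r
    M = np.einsum("knp,lnp->kl", R, R)

    mu, vecs = scipy.linalg.eigh(M)
    degenerate = bool(q > 1 and mu[1] - mu[0] < _TIE_TOL * max(mu[-1], 1.0))
    if degenerate:
        warnings.warn("layout is not unique: tied leading eigenvalues "
                      "(axes may be pairwise independent)",
                      DegenerateLayoutWarning)
    theta = vecs[:, 0] * np.sqrt(n_eff)

    # map back to per-axis scale vectors
    gamma: list[np.ndarray] = [np.zeros(Zs[j].shape[1]) for j in range(p)]
    k = 0
    for (j, r), T in zip(blocks, transforms):
        gamma[j] = T @ theta[k:k + r]
        k += r
    # sign convention: first nonzero element of the stacked scales positive
    stacked = np.concatenate([gamma[j] for j in fit_cols]) if fit_cols else theta
    nz = np.nonzero(np.abs(stacked) > 1e-12)[0]
    if nz.size and stacked[nz[0]] < 0:
        theta = -theta
        for j in range(p):
            gamma[j] = -gamma[j]

    # final locations/levels at the optimum
    S = np.zeros((n, len(fit_cols)))
    for c, j in enumerate(fit_cols):
        S[:, c] = Zs[j] @ gamma[j]
    alpha_fit, h = _solve_locations(Wf, S, m_safe, pinvA)
    Q = float((Wf * (S + alpha_fit[None, :] - h[:, None]) ** 2).sum())
    lam = 1.0 - Q / n_eff

    # assemble full-axis coordinates (passive placement of unfitted axes)
    alpha = np.zeros(p)
    for c, j in enumerate(fit_cols):
        alpha[j] = alpha_fit[c]
    for j in range(p):
        if in_fit[j]:
            continue
        w, Z = designs[j][0], Zs[j]
        nw = w.sum()
        if nw == 0:
            continue
        # unconstrained LS of h on this axis's encoding
        lhs = Z.T @ (w[:, None] * Z)
        rhs = Z.T @ (w * h)
        gamma[j] = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
        alpha[j] = (w * (h - Z @ gamma[j])).sum() / nw

    # global vertical centering: weighted mean of all coordinates = 0
    Y = np.full((n, p), np.nan)
    codes = np.full((n, p), -1, dtype=np.int64)
    for j in range(p):
        w = designs[j][0]
        yj = alpha[j] + Zs[j] @ gamma[j]
        Y[:, j] = np.where(w > 0, yj, np.nan)
    wtot = W
    shift = np.nansum(np.where(wtot > 0, Y, 0.0)) / wtot.sum()
    Y -= shift
    alpha = alpha - shift
    h = np.where(kept, h - shift, np.nan)

    category_coords: list[np.ndarray | None] = []
    labels: list[list[str]] = []
    kinds: list[str] = []
    for j, enc in enumerate(axes):
        kinds.append(enc.kind)
        labels.append(list(enc.category_labels))
        if enc.kind == QUANTITATIVE:
            category_coords.append(None)
            continue
        code = enc.indicator.argmax(axis=1)
        code[enc.weight == 0] = -1
        codes[:, j] = code
        mu = designs[j][2]
        category_coords.append(alpha[j] + enc.contrast @ gamma[j] - mu @ gamma[j])

    return TextileLayout(
        alpha=alpha, gamma=gamma, category_coords=category_coords,
        y=Y, h=h, weights=wtot, codes=codes,
        eigenvalue=lam, objective=Q, n_eff=float(n_eff), kept=kept,
        axis_kinds=kinds, category_labels=labels, degenerate=degenerate,
    )


def objective_value(layout: TextileLayout) -> float:
    """Weighted sum of squared deviations of coordinates from levels."""
    W = layout.weights
    diff = np.where(W > 0, np.nan_to_num(layout.y)
                    - np.nan_to_num(layout.h)[:, None], 0.0)
    return float((W * diff ** 2).sum())


def dispersion_profile(layout: TextileLayout) -> np.ndarray:
    """Per-axis weighted standard deviation of individual coordinates.

    Near-zero dispersion marks a monomorphic axis or one in linkage
    equilibrium with all others."""
    p = layout.n_axes
    out = np.zeros(p)
    for j in range(p):
        w = layout.weights[:, j]
        nw = w.sum()
        if nw == 0:
            continue
        yj = np.where(w > 0, layout.y[:, j], 0.0)
        mu = (w * yj).sum() / nw
        out[j] = np.sqrt((w * (yj - mu) ** 2).sum() / nw)
    return out


def _discordant_pairs(x: np.ndarray, y: np.ndarray) -> int:
    """Strictly discordant pairs: (x_i-x_k)(y_i-y_k) < 0."""
    order = np.lexsort((y, x))
    xs, ys = x[order], y[order]
    # rank-compress y for the Fenwick tree
    ry = np.searchsorted(np.unique(ys), ys)
    size = ry.max() + 2
    tree = [0] * size
    def update(i):
        i += 1
        while i < size:
            tree[i] += 1
            i += i & (-i)
    def query(i):  # count of inserted values <= i
        i += 1
        s = 0
        while i > 0:
            s += tree[i]
            i -= i & (-i)
        return s
    total = 0
    inserted = 0
    i = 0
    nn = len(xs)
    while i < nn:
        k = i
        while k < nn and xs[k] == xs[i]:
            k += 1
        for t in range(i, k):      # pairs tied in x never count
            total += inserted - query(ry[t])   # earlier with strictly larger y
        for t in range(i, k):
            update(ry[t])
        inserted += k - i
        i = k
    return total


def crossing_count(layout: TextileLayout, j: int) -> int:
    """Number of unordered individual pairs whose segments between axes
    j and j+1 strictly cross (opposite vertical order at the two axes).
    Pairs with a missing endpoint are skipped."""
    if not 0 <= j < layout.n_axes - 1:
        raise IndexError("axis pair out of range")
    ok = (layout.weights[:, j] > 0) & (layout.weights[:, j + 1] > 0)
    a, b = layout.codes[ok, j], layout.codes[ok, j + 1]
    va, vb = layout.category_coords[j], layout.category_coords[j + 1]
    if va is not None and vb is not None:
        # count through the contingency table: all members of a category
        # pair share the same segment
        ca, cb = len(va), len(vb)
        tab = np.zeros((ca, cb))
        np.add.at(tab, (a, b), 1.0)
        cross = 0.0
        for s in range(ca):
            for t in range(cb):
                if tab[s, t] == 0:
                    continue
                opp = (np.sign(va[s] - va[:, None])
                       * np.sign(vb[t] - vb[None, :]) < 0)
                cross += tab[s, t] * tab[opp].sum()
        return int(round(cross / 2))
    return _discordant_pairs(layout.y[ok, j], layout.y[ok, j + 1])


def het_mid_deviation(layout: TextileLayout, j: int) -> float:
    """Signed deviation of the heterozygote coordinate from the midpoint
    of the two homozygotes, normalized by the homozygote span.

    Under Hardy-Weinberg sampling the heterozygote sits at the midpoint;
    a systematic offset flags HWE violation (e.g. excess homozygosity).
    """
    labels = layout.category_labels[j]
    if len(labels) != 3:
        raise ValueError("axis is not a fully observed diallelic SNP")
    counts = np.bincount(layout.codes[:, j][layout.codes[:, j] >= 0], minlength=3)
    if (counts == 0).any():
        raise ValueError("axis lacks a genotype class")
    v = layout.category_coords[j]
    span = v[0] - v[2]
    if span == 0:
        raise ValueError("degenerate axis: homozygotes coincide")
    return float((v[1] - (v[0] + v[2]) / 2.0) / span)


def export_layout_tsv(layout: TextileLayout, path, axis_ids: list[str] | None = None) -> None:
    """TSV dump: header with lambda and objective, one row per
    (axis, category) and one per individual level."""
    ids = axis_ids or [f"axis{j + 1}" for j in range(layout.n_axes)]
    disp = dispersion_profile(layout)
    with open(path, "w") as fh:
        fh.write(f"#eigenvalue\t{layout.eigenvalue!r}\n")
        fh.write(f"#objective\t{layout.objective!r}\n")
        fh.write("row\taxis\tcategory\talpha\tcoord\tdispersion\n")
        for j in range(layout.n_axes):
            cc = layout.category_coords[j]
            aj, dj = float(layout.alpha[j]), float(disp[j])
            if cc is None:
                fh.write(f"axis\t{ids[j]}\t<quantitative>\t{aj!r}"
                         f"\t{aj!r}\t{dj!r}\n")
                continue
            for k, lab in enumerate(layout.category_labels[j]):
                fh.write(f"axis\t{ids[j]}\t{lab}\t{aj!r}"
                         f"\t{float(cc[k])!r}\t{dj!r}\n")
        fh.write("row\tindividual\tlevel\n")
        for i, hv in enumerate(layout.h):
            if not np.isnan(hv):
                fh.write(f"level\t{i}\t{float(hv)!r}\n")
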