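"""Shared fixtures: small genotype matrices and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

import textileplot as tp

GENO_LABELS = [("A", "A"), ("A", "G"), ("G", "G")]

# printed 3x3 genotype-count table of the two-SNP HWE simulation used as
# the worked example throughout (rows: AA/Aa/aa at SNP1, cols: BB/Bb/bb);
# the aa/BB cell is 201, forced by the printed margins
# (aa row 1,465; BB column 2,859; total 10,000)
TABLE1 = np.array([
    [1567, 1757, 472],
    [1091, 2583, 1065],
    [201, 696, 568],
])


def random_genotype_matrix(rng, n, p, max_c=3, miss=0.0):
    """Random diallelic genotype matrix; columns may be degenerate."""
    pairs = np.empty((n, p), dtype=object)
    for j in range(p):
        c = int(rng.integers(2, max_c + 1))
        for i in range(n):
            if miss and rng.random() < miss:
                pairs[i, j] = None
            else:
                pairs[i, j] = GENO_LABELS[int(rng.integers(0, c))]
    return tp.from_allele_pairs(pairs, [f"s{j}" for j in range(p)])


def matrix_from_table(table=TABLE1):
    """Expand a 3x3 genotype-count table into a two-SNP GenotypeMatrix."""
    table = np.asarray(table)
    rows = [(i, k) for i in range(3) for k in range(3)
            for _ in range(int(table[i, k]))]
    pairs = np.empty((len(rows), 2), dtype=object)
    for r, (i, k) in enumerate(rows):
        pairs[r, 0] = GENO_LABELS[i]
        pairs[r, 1] = GENO_LABELS[k]
    return tp.from_allele_pairs(pairs, ["snp1", "snp2"])


def drop_sparse_individuals(encs):
    """Remove individuals observed on fewer than two axes (the solver's
    own preprocessing), so oracles solve the same problem."""
    W = np.column_stack([e.weight for e in encs])
    kept = W.sum(axis=1) >= 2
    out = []
    for e in encs:
        out.append(tp.AxisEncoding(
            e.indicator[kept] if e.indicator is not None else None,
            e.contrast, np.asarray(e.weight, float)[kept],
            e.category_labels, e.kind,
            e.raw[kept] if e.raw is not None else None))
    return out


def brute_force_layout(encs, n_starts=8, seed=0):
    """Multi-start SLSQP minimization of the horizontalization objective
    under the dispersion constraint, over the full variable set
    (scales, locations, levels).  Independent of the eigen solver."""
    from scipy.optimize import NonlinearConstraint, minimize

    encs = drop_sparse_individuals(encs)
    rng = np.random.default_rng(seed)
    n = len(encs[0].weight)
    p = len(encs)
    ks = [e.contrast.shape[1] for e in encs]
    q = sum(ks)
    W = np.column_stack([e.weight for e in encs])
    Zs = [e.indicator @ e.contrast for e in encs]
    n_eff = W.sum()

    def unpack(x):
        g, o = [], 0
        for k in ks:
            g.append(x[o:o + k])
            o += k
        return g, x[o:o + p], x[o + p:]

    def ys(x):
        g, a, _ = unpack(x)
        return [a[j] + Zs[j] @ g[j] for j in range(p)]

    def obj(x):
        _, _, h = unpack(x)
        return sum((W[:, j] * (y - h) ** 2).sum() for j, y in enumerate(ys(x)))

    def con(x):
        tot = 0.0
        for j, y in enumerate(ys(x)):
            w = W[:, j]
            nw = w.sum()
            if nw == 0:
                continue
            mu = (w * y).sum() / nw
            tot += (w * (y - mu) ** 2).sum()
        return tot

    best = np.inf
    for _ in range(n_starts):
        x0 = rng.standard_normal(q + p + n)
        res = minimize(obj, x0, method="SLSQP",
                       constraints=[NonlinearConstraint(con, n_eff, n_eff)],
                       options={"maxiter": 2000, "ftol": 1e-14})
        if res.success and res.fun < best:
            best = float(res.fun)
    return best


@pytest.fixture
def table1_gm():
    return matrix_from_table()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
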