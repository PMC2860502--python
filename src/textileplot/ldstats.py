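"""Two-locus linkage disequilibrium statistics.

D = p_AB - p_A p_B measures the covariance between alleles at two loci;
D' = D / D_max normalizes by the maximum attainable at the given allele
frequencies, and r^2 = D^2 / (p_A q_A p_B q_B) is the squared allelic
correlation.  From unphased genotypes, haplotype frequencies are first
estimated by a two-locus EM under HWE (only the double heterozygote is
ambiguous), then the closed-form identities are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genodata import MISSING, GenotypeMatrix

_EM_TOL = 1e-10
_EM_MAX_ITER = 10_000


class MonomorphicLocusError(ValueError):
    """LD is undefined when a locus has a single allele."""


def ld_from_hapfreqs(pAB: float, pA: float, pB: float
                     ) -> tuple[float, float, float]:
    """Exact (D, D', r^2) from haplotype and allele frequencies.

    D_max is min(pA*qB, qA*pB) for D > 0 and min(pA*pB, qA*qB) for D < 0;
    D = 0 yields D' = r^2 = 0 by convention.
    """
    for name, v in (("pAB", pAB), ("pA", pA), ("pB", pB)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} outside [0, 1]")
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MonomorphicLocusError("allele frequency 0 or 1")
    eps = 1e-12
    if pAB > min(pA, pB) + eps or pAB < max(0.0, pA + pB - 1.0) - eps:
        raise ValueError("pAB violates the Frechet bounds")
    qA, qB = 1.0 - pA, 1.0 - pB
    D = pAB - pA * pB
    if D == 0.0:
        return 0.0, 0.0, 0.0
    Dmax = min(pA * qB, qA * pB) if D > 0 else min(pA * pB, qA * qB)
    dprime = D / Dmax
    r2 = D * D / (pA * qA * pB * qB)
    return D, dprime, r2


def _dosage(gm: GenotypeMatrix, j: int) -> tuple[np.ndarray, str]:
    """Minor-allele dosage (0/1/2, -1 missing) for a diallelic SNP axis."""
    ax = gm.axes[j]
    alleles = gm.alleles_of(j)
    if len(alleles) != 2:
        raise MonomorphicLocusError(
            f"locus {ax.id}: LD requires exactly two alleles")
    minor = alleles[1]
    dose = np.full(gm.n, -1, dtype=np.int64)
    per_cat = [lab.split("/").count(minor) for lab in ax.labels]
    obs = gm.codes[:, j] != MISSING
    dose[obs] = np.asarray(per_cat)[gm.codes[obs, j]]
    return dose, minor


def two_locus_em(table: np.ndarray, tol: float = _EM_TOL,
                 max_iter: int = _EM_MAX_ITER) -> np.ndarray:
    """ML haplotype frequencies (pAB, pAb, paB, pab) under HWE by EM from
    a 3x3 genotype-count table indexed by dosage of the 'a'/'b' alleles.

    Initialized at linkage-equilibrium products; converges when no
    frequency moves by more than *tol*.
    """
    table = np.asarray(table, dtype=float)
    ntot = table.sum()
    if ntot == 0:
        raise ValueError("empty genotype table")
    # allele frequencies of the second-listed alleles a/b
    pa = (table * np.arange(3)[:, None]).sum() / (2 * ntot)
    pb = (table * np.arange(3)[None, :]).sum() / (2 * ntot)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise MonomorphicLocusError("monomorphic locus in observed subsample")
    # haplotypes over (first, second) alleles: AB, Ab, aB, ab
    f = np.array([(1 - pa) * (1 - pb), (1 - pa) * pb, pa * (1 - pb), pa * pb])
    # only the double heterozygote cell has an ambiguous phase
    for _ in range(max_iter):
        hap = _expected_hap_counts(table, f)
        fn = hap / hap.sum()
        if np.max(np.abs(fn - f)) < tol:
            return fn
        f = fn
    raise RuntimeError("two-locus EM failed to converge")


def _expected_hap_counts(table: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Expected haplotype counts given current frequencies.

    Indexing: haplotype (x, y) -> 2*x + y with x the dosage contribution
    at locus 1 (0 = allele A, 1 = allele a), y likewise at locus 2.
    """
    hap = np.zeros(4)
    for i in range(3):
        for k in range(3):
            cnt = table[i, k]
            if cnt == 0:
                continue
            if i == 1 and k == 1:
                # double het: AB/ab vs Ab/aB split by relative likelihood
                w_cis = f[0] * f[3]
                w_trans = f[1] * f[2]
                tot = w_cis + w_trans
                pc = 0.5 if tot == 0 else w_cis / tot
                hap[0] += cnt * pc
                hap[3] += cnt * pc
                hap[1] += cnt * (1 - pc)
                hap[2] += cnt * (1 - pc)
                continue
            # unambiguous cell: the two haplotypes are determined
            x1 = [0, 0] if i == 0 else ([0, 1] if i == 1 else [1, 1])
            y1 = [0, 0] if k == 0 else ([0, 1] if k == 1 else [1, 1])
            hap[2 * x1[0] + y1[0]] += cnt
            hap[2 * x1[1] + y1[1]] += cnt
    return hap


def ld_from_genotypes(gm: GenotypeMatrix, j: int, k: int,
                      method: str = "em") -> tuple[float, float]:
    """(D', r^2) between diallelic loci j and k via two-locus EM."""
    if method != "em":
        raise ValueError(f"unknown method: {method!r}")
    dj, _ = _dosage(gm, j)
    dk, _ = _dosage(gm, k)
    ok = (dj >= 0) & (dk >= 0)
    if ok.sum() < 2:
        raise ValueError("fewer than two individuals observed at both loci")
    table = np.zeros((3, 3))
    np.add.at(table, (dj[ok], dk[ok]), 1.0)
    f = two_locus_em(table)
    # f indexed over (major/minor at j) x (major/minor at k); use the
    # major alleles as A and B
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    _, dprime, r2 = ld_from_hapfreqs(f[0], pA, pB)
    return abs(dprime), r2


@dataclass
class LDMatrix:
    """Pairwise D' and r^2 with per-locus metadata."""

    ids: list[str]
    dprime: np.ndarray
    r2: np.ndarray
    maf: np.ndarray
    method: str = "em"

    def to_long_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("locus_i\tlocus_j\tDprime\tr2\n")
            p = len(self.ids)
            for a in range(p):
                for b in range(a + 1, p):
                    fh.write(f"{self.ids[a]}\t{self.ids[b]}\t"
                             f"{float(self.dprime[a, b])!r}\t"
                             f"{float(self.r2[a, b])!r}\n")

    def to_square_tsv(self, path, stat: str = "r2") -> None:
        mat = self.r2 if stat == "r2" else self.dprime
        with open(path, "w") as fh:
            fh.write(f"#method\t{self.method}\n")
            fh.write("locus\t" + "\t".join(self.ids) + "\n")
            for a, lid in enumerate(self.ids):
                fh.write(lid + "\t" + "\t".join(repr(float(v)) for v in mat[a]) + "\n")


def pairwise_ld(gm: GenotypeMatrix) -> LDMatrix:
    """All-pairs (D', r^2); multi-allelic or monomorphic loci get NaN."""
    snp_cols = [j for j in range(gm.p) if gm.axes[j].kind == "snp"]
    p = len(snp_cols)
    dp = np.full((p, p), np.nan)
    r2 = np.full((p, p), np.nan)
    maf = np.full(p, np.nan)
    usable = []
    for a, j in enumerate(snp_cols):
        alleles = gm.alleles_of(j)
        if len(alleles) == 2:
            dose, _ = _dosage(gm, j)
            obs = dose >= 0
            if obs.any():
                maf[a] = dose[obs].sum() / (2.0 * obs.sum())
            usable.append(a)
            dp[a, a] = r2[a, a] = 1.0
    for ia, a in enumerate(usable):
        for b in usable[ia + 1:]:
            try:
                d, r = ld_from_genotypes(gm, snp_cols[a], snp_cols[b])
            except (MonomorphicLocusError, ValueError):
                continue
            dp[a, b] = dp[b, a] = d
            r2[a, b] = r2[b, a] = r
    return LDMatrix([gm.axes[j].id for j in snp_cols], dp, r2, maf)
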