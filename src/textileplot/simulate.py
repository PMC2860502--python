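"""Hardy-Weinberg genotype simulation from haplotype pools.

Each simulated individual is two independent draws from a haplotype
pool, so genotype frequencies follow HWE exactly.  Pools are given
either explicitly (haplotype strings with frequencies) or as an LD block
specification: per-locus minor allele frequency and target D' for
adjacent pairs within and between blocks.  The multilocus pool in the
block case is a first-order Markov chain over loci — adjacent pairs
attain the requested D' exactly, longer-range D' is whatever the chain
implies (the targets are only stated for adjacency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genodata import GenotypeMatrix, from_allele_pairs
from .ldstats import ld_from_hapfreqs


@dataclass
class SimConfig:
    """Haplotype-pool simulation settings.

    Exactly one of ``haplotypes`` (mapping haplotype string -> frequency)
    or ``block_sizes`` must be given.  ``maf``/``dprime_within``/
    ``dprime_between`` parameterize the block construction; alleles are
    written 'A' (major) and 'B' (minor) per locus.
    """

    n: int = 10_000
    seed: int = 0
    haplotypes: dict[str, float] | None = None
    block_sizes: list[int] | None = None
    maf: float = 0.4
    dprime_within: float = 0.8
    dprime_between: float = 0.1
    locus_ids: list[str] | None = None
    positions: list[int] | None = None

    def validate(self) -> None:
        if (self.haplotypes is None) == (self.block_sizes is None):
            raise ValueError("give exactly one of haplotypes or block_sizes")
        if self.haplotypes is not None:
            tot = sum(self.haplotypes.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"haplotype frequencies sum to {tot}, not 1")
            lens = {len(h) for h in self.haplotypes}
            if len(lens) != 1:
                raise ValueError("haplotype strings must share one length")
        if self.n < 1:
            raise ValueError("n must be positive")


def hapfreqs_from_ld(maf1: float, maf2: float, dprime: float,
                     sign: int = 1) -> tuple[float, float, float, float]:
    """Two-locus haplotype frequencies (pAB, pAb, paB, pab) realizing the
    requested MAFs and |D'|, with A/B the major alleles and D = sign *
    dprime * Dmax."""
    if not 0.0 < maf1 <= 0.5 or not 0.0 < maf2 <= 0.5:
        raise ValueError("MAF must lie in (0, 0.5]")
    if not 0.0 <= dprime <= 1.0:
        raise ValueError("|D'| must lie in [0, 1]")
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    pA, pB = 1.0 - maf1, 1.0 - maf2
    qA, qB = maf1, maf2
    Dmax = min(pA * qB, qA * pB) if sign > 0 else min(pA * pB, qA * qB)
    D = sign * dprime * Dmax
    freqs = (pA * pB + D, pA * qB - D, qA * pB - D, qA * qB + D)
    if min(freqs) < -1e-12:
        raise ValueError("infeasible (MAF, D') combination")
    return tuple(max(f, 0.0) for f in freqs)


def _pool_from_blocks(cfg: SimConfig) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-locus marginals and adjacent-pair conditionals of the Markov
    haplotype chain; returns (list of 2x2 conditional P(next|this), start
    marginal).  Allele index 0 = major 'A', 1 = minor 'B'."""
    sizes = cfg.block_sizes
    L = sum(sizes)
    boundaries = set(np.cumsum(sizes)[:-1])  # chain positions where blocks switch
    conds = []
    for j in range(L - 1):
        dp = cfg.dprime_between if (j + 1) in boundaries else cfg.dprime_within
        pAB, pAb, paB, pab = hapfreqs_from_ld(cfg.maf, cfg.maf, dp, sign=1)
        joint = np.array([[pAB, pAb], [paB, pab]])
        cond = joint / joint.sum(axis=1, keepdims=True)
        conds.append(cond)
    start = np.array([1.0 - cfg.maf, cfg.maf])
    return conds, start


def _sample_block_haplotypes(cfg: SimConfig, rng: np.random.Generator,
                             count: int) -> np.ndarray:
    conds, start = _pool_from_blocks(cfg)
    L = len(conds) + 1
    haps = np.empty((count, L), dtype=np.int64)
    haps[:, 0] = rng.random(count) < start[1]
    for j, cond in enumerate(conds):
        u = rng.random(count)
        p_minor = cond[haps[:, j], 1]
        haps[:, j + 1] = u < p_minor
    return haps


def simulate_genotypes(cfg: SimConfig
                       ) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Draw n individuals (two haplotypes each) under HWE.

    Returns the genotype matrix and the true haplotype pair per
    individual (retained for testing and truth export); output is
    bit-reproducible for a fixed seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if cfg.haplotypes is not None:
        names = sorted(cfg.haplotypes)
        freqs = np.array([cfg.haplotypes[h] for h in names])
        L = len(names[0])
        draws = rng.choice(len(names), size=(cfg.n, 2), p=freqs / freqs.sum())
        hap_strings = [(names[a], names[b]) for a, b in draws]
    else:
        L = sum(cfg.block_sizes)
        haps = _sample_block_haplotypes(cfg, rng, 2 * cfg.n)
        alph = np.array(["A", "B"])
        hap_strings = [("".join(alph[haps[2 * i]]), "".join(alph[haps[2 * i + 1]]))
                       for i in range(cfg.n)]
    pairs = np.empty((cfg.n, L), dtype=object)
    for i, (h1, h2) in enumerate(hap_strings):
        for j in range(L):
            pairs[i, j] = (h1[j], h2[j])
    ids = cfg.locus_ids or [f"snp{j + 1}" for j in range(L)]
    pos = cfg.positions or list(range(1, L + 1))
    gm = from_allele_pairs(pairs, ids, positions=pos)
    return gm, hap_strings


def simulate_blocks(cfg: SimConfig) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """HWE draw from the Markov block construction (block spec required)."""
    if cfg.block_sizes is None:
        raise ValueError("block specification required")
    return simulate_genotypes(cfg)


def export_truth_tsv(hap_pairs: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\thap1\thap2\n")
        for i, (a, b) in enumerate(hap_pairs):
            fh.write(f"ind{i + 1}\t{a}\t{b}\n")
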