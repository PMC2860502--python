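"""Homozygous-stretch haplotype approximation and multi-locus EM.

An individual homozygous at every locus of a range carries two copies of
the same haplotype there; under HWE the expected proportion of such
individuals is the squared haplotype frequency, so sqrt(count / N)
approximates the frequency without any phasing.  A standard multi-locus
EM estimator over the 2^L haplotype space serves as the comparison
reference; the approximation degrades as haplotype diversity grows and
LD weakens.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .genodata import GenotypeMatrix


class IncompatibleHaplotypeError(ValueError):
    """A genotype cannot be decomposed against the given haplotype."""

    def __init__(self, locus: str):
        super().__init__(f"haplotype incompatible with genotype at locus {locus}")
        self.locus = locus


@dataclass
class HaplotypeEstimate:
    haplotype: str
    stretch_count: int
    sqrt_estimate: float
    em_estimate: float | None = None


def _range_pairs(gm: GenotypeMatrix, loci: range | list[int]
                 ) -> tuple[list[int], np.ndarray]:
    loci = list(loci)
    if not loci:
        raise ValueError("empty locus range")
    for j in loci:
        if gm.axes[j].kind != "snp":
            raise ValueError(f"axis {gm.axes[j].id} is not a SNP")
    full = np.ones(gm.n, dtype=bool)
    for j in loci:
        full &= gm.codes[:, j] >= 0
    return loci, full


def homozygous_stretches(gm: GenotypeMatrix, loci) -> list[HaplotypeEstimate]:
    """Group fully-homozygous individuals over *loci* by implied haplotype.

    Individuals with any missing call in the range are excluded both from
    counting and from N; estimates are sqrt(count / N), sorted by
    descending count (ties by haplotype string).
    """
    loci, full = _range_pairs(gm, loci)
    N = int(full.sum())
    counts: dict[str, int] = {}
    for i in np.nonzero(full)[0]:
        hap = []
        for j in loci:
            a, b = gm.allele_pair(i, j)
            if a != b:
                hap = None
                break
            hap.append(a)
        if hap is not None:
            s = "".join(hap)
            counts[s] = counts.get(s, 0) + 1
    out = [HaplotypeEstimate(s, c, float(np.sqrt(c / N)) if N else 0.0)
           for s, c in counts.items()]
    out.sort(key=lambda e: (-e.stretch_count, e.haplotype))
    return out


def subtract_stretch(gm: GenotypeMatrix, individual: int, known_haplotype: str,
                     loci=None) -> str:
    """Complementary haplotype of one individual given a known haplotype.

    At each locus the complement is the individual's other allele; purely
    deterministic.  Raises :class:`IncompatibleHaplotypeError` naming the
    first locus whose genotype cannot contain the known allele.
    """
    loci = list(loci) if loci is not None else [
        j for j in range(gm.p) if gm.axes[j].kind == "snp"]
    if len(known_haplotype) != len(loci):
        raise ValueError("haplotype length does not match locus range")
    comp = []
    for a_known, j in zip(known_haplotype, loci):
        pair = gm.allele_pair(individual, j)
        if pair is None:
            raise IncompatibleHaplotypeError(gm.axes[j].id)
        a, b = pair
        if a_known == a:
            comp.append(b)
        elif a_known == b:
            comp.append(a)
        else:
            raise IncompatibleHaplotypeError(gm.axes[j].id)
    return "".join(comp)


def em_haplotype_freqs(gm: GenotypeMatrix, loci, tol: float = 1e-10,
                       max_iter: int = 10_000) -> dict[str, float]:
    """ML haplotype frequencies under HWE by EM over diplotype expansions.

    Restricted to diallelic loci and ranges of at most 12 loci (2^L
    haplotype space).  Individuals with missing calls in the range are
    excluded.  The log-likelihood is non-decreasing across iterations.
    """
    loci, full = _range_pairs(gm, loci)
    L = len(loci)
    if L > 12:
        raise ValueError("haplotype space too large (more than 12 loci)")
    alleles_per = []
    for j in loci:
        al = gm.alleles_of(j)
        if len(al) > 2:
            raise ValueError(f"locus {gm.axes[j].id} is not diallelic")
        alleles_per.append(al if len(al) == 2 else al * 2)

    # group individuals by multilocus genotype, expand each into the
    # compatible (hap, hap) index pairs
    geno_groups: dict[tuple, int] = {}
    for i in np.nonzero(full)[0]:
        key = tuple(gm.allele_pair(i, j) for j in loci)
        geno_groups[key] = geno_groups.get(key, 0) + 1
    if not geno_groups:
        raise ValueError("no fully observed individual in range")

    hap_index: dict[str, int] = {}

    def hidx(hap: tuple[str, ...]) -> int:
        s = "".join(hap)
        if s not in hap_index:
            hap_index[s] = len(hap_index)
        return hap_index[s]

    expansions = []
    for key, cnt in geno_groups.items():
        het = [j for j, (a, b) in enumerate(key) if a != b]
        pairs = []
        if het:
            # fix the first het locus's phase to avoid double counting
            for flips in itertools.product((0, 1), repeat=len(het) - 1):
                h1, h2 = list(zip(*key))
                h1, h2 = list(h1), list(h2)
                for f, jh in zip((0,) + flips, het):
                    if f:
                        h1[jh], h2[jh] = h2[jh], h1[jh]
                pairs.append((hidx(tuple(h1)), hidx(tuple(h2))))
        else:
            h = tuple(a for a, _ in key)
            pairs.append((hidx(h), hidx(h)))
        expansions.append((cnt, pairs))

    H = len(hap_index)
    f = np.full(H, 1.0 / H)
    n2 = 2.0 * sum(cnt for cnt, _ in expansions)
    for _ in range(max_iter):
        counts = np.zeros(H)
        for cnt, pairs in expansions:
            w = np.array([f[a] * f[b] * (1.0 if a == b else 2.0)
                          for a, b in pairs])
            tot = w.sum()
            if tot == 0:
                w = np.full(len(pairs), 1.0 / len(pairs))
            else:
                w = w / tot
            for (a, b), wk in zip(pairs, w):
                counts[a] += cnt * wk
                counts[b] += cnt * wk
        fn = counts / n2
        if np.max(np.abs(fn - f)) < tol:
            f = fn
            break
        f = fn
    else:
        raise RuntimeError("multi-locus EM failed to converge")
    names = sorted(hap_index, key=hap_index.get)
    out = {s: float(f[hap_index[s]]) for s in names if f[hap_index[s]] > 0}
    return dict(sorted(out.items(), key=lambda kv: (-kv[1], kv[0])))


def export_haplotypes_tsv(estimates: list[HaplotypeEstimate], path) -> None:
    with open(path, "w") as fh:
        fh.write("haplotype\tstretch_count\tsqrt_estimate\tem_estimate\n")
        for e in estimates:
            em = "" if e.em_estimate is None else repr(e.em_estimate)
            fh.write(f"{e.haplotype}\t{e.stretch_count}\t{e.sqrt_estimate!r}\t{em}\n")
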