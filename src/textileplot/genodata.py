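"""Genotype/phenotype containers and categorical encoding.

The textile plot treats every column (SNP or phenotype) as a categorical
axis.  A diploid SNP genotype is an unordered allele pair; each distinct
pair is one category.  Downstream modules consume the indicator-matrix
encoding produced here: an n x c_j 0/1 matrix whose row i is the unit
vector of individual i's category (all zeros when the call is missing),
a full-column-rank contrast matrix mapping the c_j categories to c_j - 1
free coordinates, and a 0/1 weight vector marking observed entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

MISSING = -1

SNP = "snp"
CATEGORICAL = "categorical_phenotype"
QUANTITATIVE = "quantitative_phenotype"

_MISSING_TOKENS = {"", ".", "..", "NA", "na", "nan", "./.", ".|.", "N/A"}


class GenotypeDataError(ValueError):
    """Malformed or unsupported genotype input."""


@dataclass
class AxisMeta:
    """Per-column metadata: identity, genomic position, category labels."""

    id: str
    chrom: str = "1"
    pos: int = 0
    labels: list[str] = field(default_factory=list)
    kind: str = SNP

    @property
    def n_categories(self) -> int:
        return len(self.labels)


@dataclass
class GenotypeMatrix:
    """n individuals x p axes of category codes plus per-axis metadata.

    ``codes[i, j]`` is an integer in ``[0, c_j)`` or :data:`MISSING`.
    Quantitative phenotype axes keep raw real values (NaN = missing) in
    ``quant[j]``; their codes column is all MISSING and ignored.
    """

    codes: np.ndarray
    axes: list[AxisMeta]
    samples: list[str]
    quant: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2:
            raise GenotypeDataError("codes must be 2-D (individuals x axes)")
        n, p = self.codes.shape
        if p != len(self.axes):
            raise GenotypeDataError("axis metadata length mismatch")
        if n != len(self.samples):
            raise GenotypeDataError("sample list length mismatch")
        if len(set(self.samples)) != n:
            raise GenotypeDataError("duplicate sample identifiers")
        ids = [a.id for a in self.axes]
        if len(set(ids)) != p:
            raise GenotypeDataError("duplicate locus identifiers")
        for j, ax in enumerate(self.axes):
            if ax.kind == QUANTITATIVE:
                continue
            col = self.codes[:, j]
            if ax.n_categories < 1:
                raise GenotypeDataError(f"axis {ax.id}: no categories")
            ok = (col == MISSING) | ((col >= 0) & (col < ax.n_categories))
            if not ok.all():
                raise GenotypeDataError(f"axis {ax.id}: code out of range")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def p(self) -> int:
        return self.codes.shape[1]

    def alleles_of(self, j: int) -> list[str]:
        """Distinct allele labels of SNP axis *j*, major first."""
        seen: list[str] = []
        for lab in self.axes[j].labels:
            for a in lab.split("/"):
                if a not in seen:
                    seen.append(a)
        return seen

    def allele_pair(self, i: int, j: int) -> tuple[str, str] | None:
        """The unordered allele pair of individual *i* at axis *j*."""
        c = self.codes[i, j]
        if c == MISSING:
            return None
        a, b = self.axes[j].labels[c].split("/")
        return (a, b)

    def subset_axes(self, idx: list[int]) -> "GenotypeMatrix":
        axes = [replace(self.axes[j]) for j in idx]
        quant = {k: self.quant[j].copy() for k, j in enumerate(idx) if j in self.quant}
        return GenotypeMatrix(self.codes[:, idx].copy(), axes, list(self.samples), quant)


@dataclass
class AxisEncoding:
    """Indicator/contrast/weight encoding of one axis.

    For a quantitative axis ``indicator``/``contrast`` are None and
    ``raw`` carries the real values (the solver centers and standardizes
    them); everything else follows the categorical scheme.
    """

    indicator: np.ndarray | None
    contrast: np.ndarray | None
    weight: np.ndarray
    category_labels: list[str]
    kind: str = SNP
    raw: np.ndarray | None = None

    @property
    def n_categories(self) -> int:
        return len(self.category_labels)


def helmert_contrast(c: int) -> np.ndarray:
    """Helmert-style c x (c-1) contrast: column k opposes the first k+1
    categories to category k+1.  Columns sum to zero, hence are linearly
    independent of the ones vector, and have rank c-1."""
    B = np.zeros((c, max(c - 1, 0)))
    for k in range(c - 1):
        B[: k + 1, k] = 1.0
        B[k + 1, k] = -(k + 1.0)
    return B


def encode_axis(gm: GenotypeMatrix, j: int) -> AxisEncoding:
    """Indicator-matrix encoding of column *j* of *gm*."""
    ax = gm.axes[j]
    if ax.kind == QUANTITATIVE:
        raw = np.asarray(gm.quant[j], dtype=float)
        weight = (~np.isnan(raw)).astype(float)
        return AxisEncoding(None, None, weight, [], kind=ax.kind, raw=raw)
    col = gm.codes[:, j]
    c = ax.n_categories
    ind = np.zeros((gm.n, c))
    obs = col != MISSING
    ind[np.nonzero(obs)[0], col[obs]] = 1.0
    return AxisEncoding(ind, helmert_contrast(c), obs.astype(float),
                        list(ax.labels), kind=ax.kind)


def encode_all(gm: GenotypeMatrix) -> list[AxisEncoding]:
    return [encode_axis(gm, j) for j in range(gm.p)]


# ---------------------------------------------------------------------------
# construction from raw allele calls

def _rank_alleles(pairs: list[tuple[str, str] | None]) -> list[str]:
    # major allele first: descending count, ties lexicographic
    counts: dict[str, int] = {}
    for pr in pairs:
        if pr is None:
            continue
        for a in pr:
            counts[a] = counts.get(a, 0) + 1
    return sorted(counts, key=lambda a: (-counts[a], a))


def _categories_for(pairs: list[tuple[str, str] | None]) -> list[tuple[str, str]]:
    alleles = _rank_alleles(pairs)
    rank = {a: r for r, a in enumerate(alleles)}
    if len(alleles) == 2:
        # biallelic: always the full (major-hom, het, minor-hom) triple
        a, b = alleles
        return [(a, a), (a, b), (b, b)]
    observed = {tuple(sorted(pr, key=lambda x: (rank[x], x))) for pr in pairs if pr is not None}
    return sorted(observed, key=lambda pr: (rank[pr[0]], rank[pr[1]]))


def from_allele_pairs(
    pairs: np.ndarray,
    ids: list[str],
    samples: list[str] | None = None,
    chroms: list[str] | None = None,
    positions: list[int] | None = None,
    sort_by_position: bool = True,
) -> GenotypeMatrix:
    """Build a :class:`GenotypeMatrix` from an n x p object array of
    unordered allele pairs (tuples of two strings, or None for missing).

    Genotype categories are ordered by descending sample allele frequency
    (ties lexicographic); biallelic loci always carry the full
    homozygote/heterozygote/homozygote label triple.
    """
    pairs = np.asarray(pairs, dtype=object)
    n, p = pairs.shape
    samples = samples or [f"ind{i + 1}" for i in range(n)]
    chroms = chroms or ["1"] * p
    positions = positions if positions is not None else list(range(1, p + 1))
    codes = np.full((n, p), MISSING, dtype=np.int64)
    axes = []
    for j in range(p):
        col = [pairs[i, j] for i in range(n)]
        cats = _categories_for(col)
        rank = {a: r for r, a in enumerate(_rank_alleles(col))}
        index = {cat: k for k, cat in enumerate(cats)}
        for i, pr in enumerate(col):
            if pr is None:
                continue
            key = tuple(sorted(pr, key=lambda x: (rank[x], x)))
            if key not in index:
                raise GenotypeDataError(f"locus {ids[j]}: unseen genotype {key}")
            codes[i, j] = index[key]
        axes.append(AxisMeta(ids[j], chroms[j], int(positions[j]),
                             ["/".join(c) for c in cats], SNP))
    gm = GenotypeMatrix(codes, axes, list(samples))
    if sort_by_position:
        order = sorted(range(p), key=lambda j: (axes[j].chrom, axes[j].pos))
        if order != list(range(p)):
            gm = gm.subset_axes(order)
    return gm


def attach_phenotype(gm: GenotypeMatrix, values, kind: str) -> GenotypeMatrix:
    """Append a phenotype axis encoded exactly like a genotype axis.

    Categorical values become categories ordered by descending frequency
    (ties lexicographic); quantitative values are kept raw (the solver
    centers them, which is what the location parameter does anyway).
    """
    values = list(values)
    if len(values) != gm.n:
        raise GenotypeDataError("phenotype length != number of individuals")
    codes = np.hstack([gm.codes, np.full((gm.n, 1), MISSING, dtype=np.int64)])
    quant = dict(gm.quant)
    if kind == QUANTITATIVE:
        raw = np.array([np.nan if v is None else float(v) for v in values])
        quant[gm.p] = raw
        meta = AxisMeta("phenotype", chrom="", pos=0, labels=[], kind=QUANTITATIVE)
    elif kind == CATEGORICAL:
        obs = [str(v) for v in values if v is not None and str(v) not in _MISSING_TOKENS]
        counts: dict[str, int] = {}
        for v in obs:
            counts[v] = counts.get(v, 0) + 1
        labels = sorted(counts, key=lambda v: (-counts[v], v))
        if len(labels) < 2:
            warnings.warn("constant phenotype: degenerate single-category axis")
        index = {v: k for k, v in enumerate(labels)}
        for i, v in enumerate(values):
            s = None if v is None else str(v)
            if s is not None and s not in _MISSING_TOKENS:
                codes[i, gm.p] = index[s]
        meta = AxisMeta("phenotype", chrom="", pos=0, labels=labels, kind=CATEGORICAL)
    else:
        raise GenotypeDataError(f"unknown phenotype kind: {kind}")
    return GenotypeMatrix(codes, gm.axes + [meta], list(gm.samples), quant)


# ---------------------------------------------------------------------------
# readers / writer

def _parse_call(token: str) -> tuple[str, str] | None:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return None
    if "/" in token or "|" in token:
        parts = token.replace("|", "/").split("/")
        if len(parts) != 2:
            raise GenotypeDataError(f"non-diploid call: {token!r}")
        a, b = parts
    elif len(token) == 2:
        a, b = token[0], token[1]
    else:
        raise GenotypeDataError(f"cannot parse genotype call: {token!r}")
    if a in {".", "0", ""} or b in {".", "0", ""}:
        return None  # half-missing treated as fully missing
    return (a, b)


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from VCF, PLINK .ped/.map, or plain TSV."""
    if format == "tsv":
        return _read_tsv(Path(path))
    if format == "vcf":
        return _read_vcf(Path(path))
    if format == "plink":
        return _read_plink(Path(path))
    raise GenotypeDataError(f"unknown format: {format!r}")


def _read_tsv(path: Path) -> GenotypeMatrix:
    chrom_line = pos_line = kind_line = None
    rows: list[list[str]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if fields[0] == "#chrom":
                chrom_line = fields[1:]
            elif fields[0] == "#pos":
                pos_line = fields[1:]
            elif fields[0] == "#kind":
                kind_line = fields[1:]
            elif header is None:
                header = fields
            else:
                rows.append(fields)
    if header is None or not rows:
        raise GenotypeDataError(f"{path}: empty TSV")
    ids = header[1:]
    samples = [r[0] for r in rows]
    n, p = len(rows), len(ids)
    kinds = kind_line or [SNP] * p
    snp_cols = [j for j in range(p) if kinds[j] == SNP]
    pairs = np.empty((n, len(snp_cols)), dtype=object)
    for i, r in enumerate(rows):
        if len(r) != p + 1:
            raise GenotypeDataError(f"{path}: row {r[0]} has {len(r) - 1} fields, expected {p}")
        for k, j in enumerate(snp_cols):
            pairs[i, k] = _parse_call(r[j + 1])
    chroms = [chrom_line[j] if chrom_line else "1" for j in snp_cols]
    poss = [int(pos_line[j]) if pos_line else k + 1 for k, j in enumerate(snp_cols)]
    gm = from_allele_pairs(pairs, [ids[j] for j in snp_cols], samples, chroms, poss)
    for j in range(p):
        if kinds[j] == CATEGORICAL:
            gm = attach_phenotype(gm, [r[j + 1] for r in rows], CATEGORICAL)
            gm.axes[-1].id = ids[j]
        elif kinds[j] == QUANTITATIVE:
            vals = [None if r[j + 1] in _MISSING_TOKENS else float(r[j + 1]) for r in rows]
            gm = attach_phenotype(gm, vals, QUANTITATIVE)
            gm.axes[-1].id = ids[j]
    return gm


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[list[tuple[str, str] | None]] = []
    ids, chroms, poss = [], [], []
    for k, var in enumerate(vcf):
        alleles = [var.REF] + list(var.ALT)
        col: list[tuple[str, str] | None] = []
        for g in var.genotypes:
            if len(g) != 3:  # [allele_a, allele_b, phased]
                raise GenotypeDataError(
                    f"non-diploid record at {var.CHROM}:{var.POS}")
            a, b = g[0], g[1]
            col.append(None if a < 0 or b < 0 else (alleles[a], alleles[b]))
        cols.append(col)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
    if not cols:
        raise GenotypeDataError(f"{path}: no variant records")
    pairs = np.empty((len(samples), len(cols)), dtype=object)
    for j, col in enumerate(cols):
        for i, pr in enumerate(col):
            pairs[i, j] = pr
    return from_allele_pairs(pairs, ids, samples, chroms, poss)


def _read_plink(path: Path) -> GenotypeMatrix:
    path = Path(path)
    base = path.with_suffix("") if path.suffix in {".ped", ".map"} else path
    ped, mp = base.with_suffix(".ped"), base.with_suffix(".map")
    ids, chroms, poss = [], [], []
    with open(mp) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            chroms.append(f[0])
            ids.append(f[1])
            poss.append(int(f[3]))
    p = len(ids)
    samples, rows = [], []
    with open(ped) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            if len(f) != 6 + 2 * p:
                raise GenotypeDataError(f"{ped}: bad field count for {f[1]}")
            samples.append(f[1])
            row = []
            for j in range(p):
                a, b = f[6 + 2 * j], f[7 + 2 * j]
                row.append(None if a == "0" or b == "0" else (a, b))
            rows.append(row)
    pairs = np.empty((len(rows), p), dtype=object)
    for i, row in enumerate(rows):
        for j, pr in enumerate(row):
            pairs[i, j] = pr
    return from_allele_pairs(pairs, ids, samples, chroms, poss)


def write_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Canonical TSV dump; ``read_genotypes(path, 'tsv')`` round-trips."""
    with open(path, "w") as fh:
        fh.write("#chrom\t" + "\t".join(a.chrom for a in gm.axes) + "\n")
        fh.write("#pos\t" + "\t".join(str(a.pos) for a in gm.axes) + "\n")
        if any(a.kind != SNP for a in gm.axes):
            fh.write("#kind\t" + "\t".join(a.kind for a in gm.axes) + "\n")
        fh.write("sample\t" + "\t".join(a.id for a in gm.axes) + "\n")
        for i, s in enumerate(gm.samples):
            cells = []
            for j, ax in enumerate(gm.axes):
                if ax.kind == QUANTITATIVE:
                    v = gm.quant[j][i]
                    cells.append("NA" if np.isnan(v) else repr(float(v)))
                else:
                    c = gm.codes[i, j]
                    if c == MISSING:
                        cells.append("./." if ax.kind == SNP else "NA")
                    else:
                        cells.append(ax.labels[c])
            fh.write(s + "\t" + "\t".join(cells) + "\n")
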