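# textileplot

Textile plots for unphased diploid SNP genotype data: a
parallel-coordinate display in which every SNP (and, optionally, a
phenotype) gets its own vertical axis, and the vertical positions of the
genotype categories on every axis are chosen *jointly* so that each
individual's polyline runs as horizontally as possible.  Linkage
disequilibrium (LD) then becomes directly visible: tightly linked SNPs
produce horizontal, non-crossing bundles; SNPs in linkage equilibrium
produce dense crossings; homozygous stretches trace out the major
haplotypes without any phasing.

The package is for statistical geneticists and visualization-minded
analysts who want an LD display that is *quantitative* — every geometric
feature (axis scale, crossing count, stretch width) is the output of a
well-defined optimization, not a styling choice.

## The model

Axis j displays its c_j genotype categories at coordinates
v_j = α_j·1 + B_j γ_j (location + contrast-scaled scales).  With
y_ij the coordinate of individual i on axis j and w_ij ∈ {0,1} marking
observed calls, the layout minimizes the horizontalization criterion

    Q(α, γ, h) = Σ_j Σ_i w_ij (y_ij − h_i)²

over all locations α_j, scales γ_j and individual levels h_i, subject to
fixing the total dispersion Σ_j Σ_i w_ij (y_ij − ȳ_j)² = ñ, the number
of observed cells.  Eliminating the levels and locations (both weighted
means at the optimum) reduces this to a generalized symmetric
eigenproblem over the stacked scales; the solver takes the extreme
eigenvector and rescales it to satisfy the constraint exactly.  On
complete data the solution coincides with the first dimension of a
multiple correspondence analysis.  See `docs/methods.md` for the full
derivation, conventions and caveats.

Supporting machinery, each a public module:

* `genodata` — VCF / PLINK ped+map / TSV readers, indicator–contrast
  encoding, phenotype attachment;
* `solver` — the layout optimizer, crossing counts, dispersion profile,
  heterozygote-midpoint diagnostic;
* `ldstats` — D, D′, r² from haplotype frequencies or from unphased
  genotypes via two-locus EM;
* `haplotypes` — homozygous-stretch detection, √(count/N) frequency
  approximation, multi-locus EM reference;
* `simulate` — HWE genotype simulation from haplotype pools or LD-block
  specs (per-locus MAF + adjacent D′);
* `cluster` — mean-absolute-deviation axis distances, ordered single
  end-linkage reordering, Newick dendrogram;
* `render` / CLI — deterministic SVG output, `textileplot` command.

## Worked example

The classic two-SNP worked example is a 3×3 genotype count table from an
HWE population of 10,000 individuals (counts: AA row 1567/1757/472, Aa
row 1091/2583/1065, aa row 201/696/568, columns BB/Bb/bb).  Expanding it
into a genotype matrix and solving:

```python
import numpy as np, textileplot as tp

counts = np.array([[1567, 1757, 472], [1091, 2583, 1065], [201, 696, 568]])
labels = [("A", "A"), ("A", "G"), ("G", "G")]
rows = [(i, k) for i in range(3) for k in range(3)
        for _ in range(counts[i, k])]
pairs = np.empty((len(rows), 2), dtype=object)
for r, (i, k) in enumerate(rows):
    pairs[r] = [labels[i], labels[k]]
gm = tp.from_allele_pairs(pairs, ["snp1", "snp2"])

layout = tp.solve_layout(tp.encode_all(gm))
print("lambda", round(layout.eigenvalue, 4), "Q", round(layout.objective, 1))
for j, cats in enumerate((["AA", "Aa", "aa"], ["BB", "Bb", "bb"])):
    for k, c in enumerate(cats):
        print(f"snp{j+1}", c, round(layout.category_coords[j][k], 3))
print("crossings", tp.crossing_count(layout, 0))
print("D'= %.3f  r2 = %.3f" % tp.ld_from_genotypes(gm, 0, 1))
```

prints

```
lambda 0.6338 Q 7324.4
snp1 AA 1.141
snp1 Aa -0.38
snp1 aa -1.728
snp2 BB 1.342
snp2 Bb -0.133
snp2 bb -1.505
crossings 5902044
D'= 0.317  r2 = 0.073
```

Read the geometry: AA lies vertically closer to BB (|1.141 − 1.342| =
0.20) than to bb (2.65), so the allelic covariance is positive; the
heterozygote segment slopes upward from Aa (−0.38) to Bb (−0.13),
reflecting the allele-frequency difference between the loci; and the
~5.9 million strictly crossing segment pairs out of ~50 million say the
LD is weak — consistent with the EM-estimated r² of 0.07.  The leading
eigenvalue λ = 0.63 ties the objective to the display budget through
Q = ñ(1 − λ) with ñ = 20,000 observed cells.

The same analysis from the shell:

```sh
textileplot simulate --blocks 2,2 --maf 0.4 --dprime-within 0.8 \
    --dprime-between 0.1 -n 10000 --seed 1 --out geno.tsv
textileplot plot geno.tsv --order cluster --out plot.svg --coords coords.tsv
textileplot ld geno.tsv --out ld.tsv
```

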