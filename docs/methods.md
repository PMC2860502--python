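# Methods

## The layout model

A textile plot is a parallel-coordinate display of p categorical axes
(SNP genotypes, optionally a phenotype) observed on n individuals.  Axis
j shows its c_j categories at vertical coordinates

    v_j = α_j · 1 + B_j γ_j ,

where α_j is a location scalar, γ_j a scale vector of length c_j − 1,
and B_j a contrast matrix — any c_j × (c_j − 1) basis of full column
rank whose columns are linearly independent of the ones vector.
Individual i's coordinate on axis j is y_ij = v_j[x_ij] for genotype
category x_ij, written through the 0/1 indicator matrix X_j as
y_j = X_j v_j.  The free parameters are chosen to minimize the weighted
sum of squared deviations of every observed coordinate from a
per-individual horizontal level h_i,

    Q = Σ_j Σ_i w_ij (y_ij − h_i)² ,

subject to fixing the total dispersion of the display,

    Σ_j Σ_i w_ij (y_ij − ȳ_j)² = ñ ,        ȳ_j = weighted mean,

with w_ij ∈ {0, 1} marking observed cells and ñ = Σ_ij w_ij the
effective number of points.  Strong linkage disequilibrium then renders
as near-horizontal, non-crossing segment bundles; linkage equilibrium as
dense crossings; absolute LD (r² = 1) as exactly horizontal segments and
complete LD (|D′| = 1) as a single homozygote-to-opposite-homozygote
crossing through the double-heterozygote segment.

### Solution

Both h_i and α_j are weighted means at any stationary point, so they can
be eliminated: the residual of the resulting two-way additive fit is
linear in the stacked scale vector γ, reducing the problem to

    minimize  γ' M γ   subject to   γ' G γ = ñ ,

where G is block diagonal with blocks Z̃_j' Z̃_j built from the
column-centered, missing-zeroed designs Z̃_j = centered(X_j B_j), and M
is assembled column-by-column from the residual fields of unit
directions (each requiring one solve of a p × p system for the
locations).  Whitening G turns this into an ordinary symmetric
eigenproblem; the smallest eigenvalue μ gives the optimum Q = ñ·μ, and
the reported leading eigenvalue is λ = 1 − μ.  On complete data λ
coincides with the leading eigenvalue of the multiple-correspondence
(homogeneity) eigenproblem, and the centered category coordinates equal
the first-dimension MCA centroid scores up to one global constant — a
property the test suite verifies against an independently constructed
MCA.

The closed-form eigen system was validated, rather than assumed: the
test suite compares the solver's optimum against a multi-start SLSQP
minimization of the raw objective over the full variable set
(γ, α, h) on 50+ random small instances, with and without missing
values, at 1e-6 relative tolerance.

### Numerical choices and degeneracies

* Directions in the null space of G (empty categories, monomorphic
  axes) move no observed point; they are fixed at zero, so monomorphic
  axes get γ_j = 0 and sit flat at their location.  Rank truncation uses
  a relative tolerance of 1e-10 on the constraint-block eigenvalues.
* The eigenvector sign is fixed so the first element of the stacked γ
  exceeding 1e-12 in magnitude is positive; eigenvalue ties within 1e-9
  (relative) raise a `DegenerateLayoutWarning` — this happens both when
  all axis pairs are empirically independent (the optimum is genuinely
  not unique) and in perfectly duplicated-axis data.
* Individuals observed on fewer than two fitted axes cannot constrain
  the fit; they are dropped with a warning and excluded from ñ.
* The dense symmetric eigensolver is used throughout; the supported
  display scale (up to a few hundred axes) keeps the stacked dimension
  Σ(c_j − 1) well inside dense-solver territory.
* Global vertical level is arbitrary (the objective and constraint are
  shift invariant); the layout is centered so the weighted mean of all
  coordinates is zero.

### Phenotype axes

A categorical phenotype is encoded exactly like a genotype axis and, by
default, participates in the fit on equal terms (`phenotype_in_fit`).
With the flag off, phenotype axes are placed passively by unconstrained
least-squares regression of the fitted levels on their encoding.  A
quantitative phenotype contributes its raw value vector in place of
X_j B_j; the vector is centered and standardized to unit weighted
variance before entering the fit, so a single quantitative axis cannot
absorb an outsized share of the constraint budget — the convention is
ours, since the raw-vector substitution leaves the scaling open.

## LD statistics

D = p_AB − p_A p_B, D′ = D / D_max with D_max = min(p_A q_B, q_A p_B)
for D > 0 and min(p_A p_B, q_A q_B) for D < 0, and r² = D² /
(p_A q_A p_B q_B); D = 0 returns D′ = r² = 0 by convention.  From
unphased genotypes the haplotype frequencies come from the two-locus EM
under HWE (only the double heterozygote is phase-ambiguous),
initialized at linkage-equilibrium products, converged when no
frequency moves by more than 1e-10, capped at 10,000 iterations.
Multi-allelic loci are excluded from pairwise LD (biallelic definitions
only) and flagged as missing in the matrix.

## Haplotype approximation

Individuals homozygous at every locus of a range carry two copies of one
haplotype; under HWE the homozygote-diplotype probability is the squared
haplotype frequency, so √(count / N) estimates the frequency, with N the
number of individuals fully observed in the range (the normalization is
our reading of "the total sum"; it makes the estimate exactly 1 for a
fixed population).  The comparison oracle is a standard multi-locus EM
over diplotype expansions (≤ 12 loci, 2^L haplotype space), whose
log-likelihood is non-decreasing per sweep.  The √-stretch approximation
is only tested — and only claimed — in the low-diversity, strong-LD
regime; it degrades as haplotype diversity grows.

## Simulator

Each individual is two independent draws from a haplotype pool, so
genotypes satisfy HWE exactly.  Pools are specified either explicitly
(strings + frequencies) or as LD blocks: per-locus MAF (default 0.4, the
value used in the reference simulations), within-block adjacent D′
(default 0.8) and cross-block adjacent D′ (default 0.1), sample size
default n = 10,000.  The multilocus pool is a first-order Markov chain
over loci whose adjacent-pair joints realize the requested (MAF, D′)
exactly; longer-range D′ is whatever the chain implies — adequate here
because the reference designs state targets only for adjacent pairs.
One integer seed drives a single `numpy` generator stream;
reproducibility is bit-for-bit.

What the generator does *not* emulate: mutation/recombination history,
allele-frequency spectra, genotyping error, population structure.
Passing tests therefore demonstrate correctness of the machinery under
clean HWE sampling, not robustness to real-data artifacts.

## Axis reordering

Distance between axes = weighted mean absolute deviation of individual
coordinates, averaged over individuals observed at both axes; pairs with
no common observation get a missing (treated as +∞) distance.  Ordering
is by ordered single end-linkage: seed with the globally closest pair,
then repeatedly attach the unplaced axis nearest to either chain end.
Ties break by original physical order (then right end), for
reproducibility.  The merge sequence forms a caterpillar dendrogram
exported as Newick, with branch lengths carrying the raw merge
distances; note the chain construction does not guarantee monotone merge
heights (a far leaf can join before a nearer pair elsewhere would have
merged under full single linkage).  Phenotype axes are excluded from
clustering and kept leftmost.

## Rendering

Plain SVG 1.1 text, deterministic for fixed inputs: one axis per column
at equal spacing, a circle per category with area strictly proportional
to the marginal count, a ribbon per adjacent genotype pair with stroke
width strictly proportional to the pair count (capped at a maximum
width, proportionality preserved within the panel), larger coordinates
upward, thickest ribbons drawn first.  Counts are embedded as `data-*`
attributes so proportionality is machine-checkable from the emitted
file.  Visual constants live in `PlotSpec`.

## Problem sizes used in the checks

Simulation-based checks run at n = 10,000 individuals and 2–6 loci
(matching the reference simulation designs); oracle-equivalence checks
use 50+ random instances at n ≤ 8, p ≤ 3, where the SLSQP reference is
reliable; clustering checks use two interleaved 3-SNP blocks at
n = 2,000.

## Known limitations

* Only the leading eigen-dimension is computed (no biplot-style second
  axis), and no confidence measures on coordinates are provided.
* The layout is unstable in the all-pairs-independent regime (flagged,
  not repaired): the method is "joint bivariate," like MCA, and cannot
  express higher-order dependence with pairwise independence.
* Stretch-based haplotype estimates are upward-reliable only in strong
  LD with few haplotypes.
* Ploidy ≠ 2, imputation, and phasing are out of scope; half-missing
  diploid calls are treated as fully missing.
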