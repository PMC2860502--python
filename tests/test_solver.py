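"""Layout optimization: oracle equivalence, invariances, geometry."""

import warnings

import numpy as np
import pytest

import textileplot as tp
from textileplot.solver import DegenerateLayoutWarning

from conftest import (GENO_LABELS, brute_force_layout, matrix_from_table,
                      random_genotype_matrix)


def constraint_residual(layout):
    """|total dispersion - n_eff| at the returned solution."""
    tot = 0.0
    for j in range(layout.n_axes):
        w = layout.weights[:, j]
        nw = w.sum()
        if nw == 0:
            continue
        y = np.where(w > 0, layout.y[:, j], 0.0)
        mu = (w * y).sum() / nw
        tot += (w * (y - mu) ** 2).sum()
    return abs(tot - layout.n_eff)


def perfect_ld_matrix(n=100, seed=0):
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 3, size=n)
    pairs = np.empty((n, 2), dtype=object)
    for i, c in enumerate(codes):
        pairs[i, 0] = pairs[i, 1] = GENO_LABELS[c]
    return tp.from_allele_pairs(pairs, ["s1", "s2"])


class TestOracleEquivalence:
    def test_random_instances_match_brute_force(self):
        """On random tiny instances (with and without missingness) the
        eigen solution attains the brute-force constrained optimum."""
        rng = np.random.default_rng(7)
        checked = 0
        trial = 0
        while checked < 10:
            trial += 1
            n = int(rng.integers(4, 9))
            p = int(rng.integers(2, 4))
            miss = 0.0 if trial % 2 else 0.15
            gm = random_genotype_matrix(rng, n, p, miss=miss)
            encs = tp.encode_all(gm)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lay = tp.solve_layout(encs)
            except ValueError:
                continue  # everything monomorphic in this draw
            bf = brute_force_layout(encs, n_starts=6, seed=trial)
            assert lay.objective <= bf + 1e-6 * max(bf, 1.0)
            assert constraint_residual(lay) < 1e-8
            checked += 1

    def test_single_instance_with_missing_matches_oracle(self, rng):
        gm = random_genotype_matrix(rng, 6, 3, miss=0.1)
        encs = tp.encode_all(gm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lay = tp.solve_layout(encs)
        bf = brute_force_layout(encs, n_starts=10, seed=99)
        assert abs(lay.objective - bf) <= 1e-6 * max(bf, 1.0)


class TestConstraintAndFeasibility:
    def test_constraint_residual_small(self, rng):
        for k in range(5):
            gm = random_genotype_matrix(rng, 30, 4, miss=0.1 * (k % 2))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lay = tp.solve_layout(tp.encode_all(gm))
            assert constraint_residual(lay) < 1e-8

    def test_random_feasible_configuration_never_beats_solver(self, rng):
        gm = random_genotype_matrix(rng, 20, 3)
        encs = tp.encode_all(gm)
        lay = tp.solve_layout(encs)
        W = np.column_stack([e.weight for e in encs])
        n_eff = W.sum()
        for _ in range(20):
            ys = []
            tot = 0.0
            for e in encs:
                v = rng.standard_normal(e.n_categories)
                y = e.indicator @ v
                mu = y.mean()
                tot += ((y - mu) ** 2).sum()
                ys.append(y)
            scale = np.sqrt(n_eff / tot)
            ys = [y * scale for y in ys]
            Y = np.column_stack(ys)
            h = Y.mean(axis=1)
            q = ((Y - h[:, None]) ** 2).sum()
            assert q >= lay.objective - 1e-9

    def test_all_monomorphic_raises(self):
        pairs = np.empty((5, 2), dtype=object)
        for i in range(5):
            pairs[i, 0] = pairs[i, 1] = ("A", "A")
        gm = tp.from_allele_pairs(pairs, ["s1", "s2"])
        with pytest.raises(ValueError, match="monomorphic"):
            tp.solve_layout(tp.encode_all(gm))

    def test_sparse_individual_dropped_with_warning(self):
        pairs = np.empty((5, 2), dtype=object)
        for i in range(5):
            pairs[i, 0] = GENO_LABELS[i % 3]
            pairs[i, 1] = GENO_LABELS[(i + 1) % 3]
        pairs[4, 0] = pairs[4, 1] = None
        gm = tp.from_allele_pairs(pairs, ["s1", "s2"])
        with pytest.warns(UserWarning, match="dropped 1 individual"):
            lay = tp.solve_layout(tp.encode_all(gm))
        assert not lay.kept[4]
        assert np.isnan(lay.y[4]).all()


class TestInvariances:
    def test_axis_order_invariance(self, rng):
        gm = random_genotype_matrix(rng, 25, 4)
        encs = tp.encode_all(gm)
        lay1 = tp.solve_layout(encs)
        perm = [2, 0, 3, 1]
        lay2 = tp.solve_layout([encs[j] for j in perm])
        np.testing.assert_allclose(lay1.objective, lay2.objective, atol=1e-9)
        np.testing.assert_allclose(lay1.eigenvalue, lay2.eigenvalue, atol=1e-9)
        for pos, j in enumerate(perm):
            np.testing.assert_allclose(
                np.abs(lay2.y[:, pos]), np.abs(lay1.y[:, j]), atol=1e-8)

    def test_contrast_invariance(self, rng):
        """Any valid contrast basis yields identical coordinates."""
        gm = random_genotype_matrix(rng, 25, 3)
        encs = tp.encode_all(gm)
        lay1 = tp.solve_layout(encs)
        alt = []
        for e in encs:
            c = e.n_categories
            # a different ones-independent basis: random full-rank mix
            mix = rng.standard_normal((c - 1, c - 1))
            while abs(np.linalg.det(mix)) < 1e-3:
                mix = rng.standard_normal((c - 1, c - 1))
            alt.append(tp.AxisEncoding(e.indicator, e.contrast @ mix,
                                       e.weight, e.category_labels, e.kind))
        lay2 = tp.solve_layout(alt)
        np.testing.assert_allclose(np.abs(lay1.y), np.abs(lay2.y), atol=1e-10)

    def test_degeneracy_warning_on_independent_axes(self):
        # two axes carrying an exactly balanced, exactly independent design
        pairs = np.empty((9, 2), dtype=object)
        k = 0
        for a in range(3):
            for b in range(3):
                pairs[k, 0] = GENO_LABELS[a]
                pairs[k, 1] = GENO_LABELS[b]
                k += 1
        gm = tp.from_allele_pairs(pairs, ["s1", "s2"])
        with pytest.warns(DegenerateLayoutWarning):
            tp.solve_layout(tp.encode_all(gm))


class TestMCACorrespondence:
    def test_category_coords_proportional_to_mca_scores(self, rng):
        """On complete data the centered category coordinates equal the
        first-dimension centroid scores of a textbook multiple
        correspondence analysis up to one global constant."""
        gm = random_genotype_matrix(rng, 40, 3)
        encs = tp.encode_all(gm)
        lay = tp.solve_layout(encs)
        n = gm.n
        C = np.eye(n) - np.ones((n, n)) / n

        def proj(X):
            X = X[:, X.sum(axis=0) > 0]  # observed categories only
            return C @ X @ np.linalg.inv(X.T @ X) @ X.T @ C

        P = sum(proj(e.indicator) for e in encs) / gm.p
        _, vecs = np.linalg.eigh(P)
        z = vecs[:, -1]
        ratios = []
        for j, e in enumerate(encs):
            occ = e.indicator.sum(axis=0) > 0
            X = e.indicator[:, occ]
            score = np.linalg.inv(X.T @ X) @ X.T @ z
            counts = X.sum(axis=0)
            v = lay.category_coords[j][occ]
            vc = v - (counts * v).sum() / counts.sum()
            sel = np.abs(score) > 1e-9
            ratios.extend(vc[sel] / score[sel])
        ratios = np.asarray(ratios)
        assert np.ptp(ratios) < 1e-8 * max(abs(ratios.mean()), 1.0)


class TestGeometry:
    def test_perfect_ld_zero_objective_zero_crossings(self):
        gm = perfect_ld_matrix()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateLayoutWarning)
            lay = tp.solve_layout(tp.encode_all(gm))
        assert lay.objective < 1e-12
        np.testing.assert_allclose(lay.category_coords[0],
                                   lay.category_coords[1], atol=1e-9)
        assert tp.crossing_count(lay, 0) == 0

    def test_table1_relative_genotype_positions(self, table1_gm):
        """Positive allelic covariance: AA sits vertically closer to BB
        than to bb, and the heterozygote segment slopes from Aa up to Bb."""
        lay = tp.solve_layout(tp.encode_all(table1_gm))
        v1, v2 = lay.category_coords
        assert abs(v1[0] - v2[0]) < abs(v1[0] - v2[2])
        assert v2[1] > v1[1]

    @pytest.mark.parametrize("haps", [
        {"AB": 0.4, "aB": 0.2, "ab": 0.4},
        {"AB": 0.5, "aB": 0.25, "ab": 0.25},
        {"AB": 0.6, "aB": 0.2, "ab": 0.2},
    ])
    def test_complete_ld_single_hom_to_opposite_hom_crossing(self, haps):
        """Complete LD (one haplotype absent, |D'| = 1, r^2 < 1): the only
        crossing is the segment joining a homozygote to the opposite-side
        homozygote, cutting the double-heterozygote segment."""
        cfg = tp.SimConfig(n=2000, seed=5, haplotypes=haps)
        gm, _ = tp.simulate_genotypes(cfg)
        lay = tp.solve_layout(tp.encode_all(gm))
        v1, v2 = lay.category_coords
        tab = tp.pair_counts(gm, [0, 1], 0)
        cells = [(s, t) for s in range(3) for t in range(3) if tab[s, t] > 0]
        crossing_pairs = [
            (c1, c2)
            for i, c1 in enumerate(cells) for c2 in cells[i + 1:]
            if (v1[c1[0]] - v1[c2[0]]) * (v2[c1[1]] - v2[c2[1]]) < 0
        ]
        assert len(crossing_pairs) == 1
        pair = set(crossing_pairs[0])
        hom_seg = [c for c in pair if c[0] in (0, 2) and c[1] in (0, 2)]
        assert len(hom_seg) == 1            # hom -> opposite-side hom
        assert (1, 1) in pair               # crossing the double het
        assert tp.crossing_count(lay, 0) > 0

    def test_inverted_halves_crossing_count(self):
        """On a fixed configuration with n/2 individuals in exactly
        inverted vertical order across two axes, every cross pair of
        segments crosses: n^2/4 crossings."""
        n = 20
        codes = np.zeros((n, 2), dtype=np.int64)
        codes[: n // 2, 0] = 0
        codes[: n // 2, 1] = 2
        codes[n // 2:, 0] = 2
        codes[n // 2:, 1] = 0
        v = np.array([1.0, 0.0, -1.0])
        y = np.column_stack([v[codes[:, 0]], v[codes[:, 1]]])
        lay = tp.TextileLayout(
            alpha=np.zeros(2), gamma=[np.zeros(2)] * 2,
            category_coords=[v, v], y=y, h=y.mean(axis=1),
            weights=np.ones((n, 2)), codes=codes, eigenvalue=0.0,
            objective=0.0, n_eff=2 * n, kept=np.ones(n, dtype=bool),
            axis_kinds=["snp", "snp"],
            category_labels=[["A/A", "A/G", "G/G"]] * 2)
        assert tp.crossing_count(lay, 0) == n * n // 4

    def test_crossing_count_matches_naive_loop(self, rng):
        gm = random_genotype_matrix(rng, 60, 3, miss=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lay = tp.solve_layout(tp.encode_all(gm))
        for j in range(2):
            naive = 0
            ok = (lay.weights[:, j] > 0) & (lay.weights[:, j + 1] > 0)
            y1, y2 = lay.y[ok, j], lay.y[ok, j + 1]
            m = len(y1)
            for a in range(m):
                for b in range(a + 1, m):
                    if (y1[a] - y1[b]) * (y2[a] - y2[b]) < 0:
                        naive += 1
            assert tp.crossing_count(lay, j) == naive


class TestObjectiveVsLd:
    def test_objective_decreases_as_ld_strengthens(self):
        """At fixed n, the optimal horizontalization objective shrinks
        monotonically as pairwise LD of the simulated data grows."""
        qs = []
        for dp in (0.1, 0.5, 0.9):
            gm, _ = tp.simulate_blocks(tp.SimConfig(
                n=3000, seed=61, block_sizes=[2], maf=0.4,
                dprime_within=dp))
            lay = tp.solve_layout(tp.encode_all(gm))
            qs.append(lay.objective)
            assert lay.objective == pytest.approx(tp.objective_value(lay),
                                                  abs=1e-8)
        assert qs[0] > qs[1] > qs[2]


class TestDispersion:
    def test_dispersion_zero_for_le_isolated_axis(self):
        # 2-SNP tight block plus one independent SNP
        cfg = tp.SimConfig(n=4000, seed=11, block_sizes=[2, 1], maf=0.4,
                           dprime_within=1.0, dprime_between=0.0)
        gm, _ = tp.simulate_blocks(cfg)
        lay = tp.solve_layout(tp.encode_all(gm))
        d = tp.dispersion_profile(lay)
        assert d[2] < 0.15 * d[:2].min()

    def test_equal_dispersion_in_exchangeable_block(self):
        haps = {"AAA": 0.6, "BBB": 0.4}
        gm, _ = tp.simulate_genotypes(tp.SimConfig(n=500, seed=3,
                                                   haplotypes=haps))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateLayoutWarning)
            lay = tp.solve_layout(tp.encode_all(gm))
        d = tp.dispersion_profile(lay)
        np.testing.assert_allclose(d, d[0], rtol=1e-9)

    def test_dispersion_tracks_leading_eigenvector_of_dosage_correlation(self):
        cfg = tp.SimConfig(n=10_000, seed=21, block_sizes=[3, 3], maf=0.4,
                           dprime_within=0.8, dprime_between=0.1)
        gm, _ = tp.simulate_blocks(cfg)
        lay = tp.solve_layout(tp.encode_all(gm))
        d = tp.dispersion_profile(lay)
        dose = np.zeros((gm.n, gm.p))
        for j in range(gm.p):
            minor = gm.alleles_of(j)[1]
            per = [lab.split("/").count(minor) for lab in gm.axes[j].labels]
            dose[:, j] = np.asarray(per)[gm.codes[:, j]]
        _, vecs = np.linalg.eigh(np.corrcoef(dose.T))
        lead = np.abs(vecs[:, -1])
        cos = d @ lead / (np.linalg.norm(d) * np.linalg.norm(lead))
        assert cos > 0.99


class TestHetMidpoint:
    def test_symmetric_counts_give_exact_midpoint(self):
        # exactly symmetric two-SNP table: heterozygote must sit midway
        table = np.array([[30, 10, 2], [10, 40, 10], [2, 10, 30]])
        gm = matrix_from_table(table)
        lay = tp.solve_layout(tp.encode_all(gm))
        for j in range(2):
            assert abs(tp.het_mid_deviation(lay, j)) < 1e-9

    def test_hwe_simulation_near_midpoint(self):
        cfg = tp.SimConfig(n=10_000, seed=13, block_sizes=[2], maf=0.4,
                           dprime_within=0.8)
        gm, _ = tp.simulate_blocks(cfg)
        lay = tp.solve_layout(tp.encode_all(gm))
        for j in range(2):
            assert abs(tp.het_mid_deviation(lay, j)) < 0.03

    def test_inbreeding_shifts_heterozygote(self):
        """Excess homozygosity (HWE violation) moves the heterozygote off
        the homozygote midpoint by more than the HWE null spread."""
        rng = np.random.default_rng(29)
        n = 4000
        f_in = 0.5  # inbreeding coefficient
        hf = tp.hapfreqs_from_ld(0.4, 0.4, 0.8, 1)
        haps = np.array(hf)
        # inbred draw: with prob f the two haplotypes are identical
        idx1 = rng.choice(4, size=n, p=haps)
        idx2 = np.where(rng.random(n) < f_in, idx1, rng.choice(4, size=n, p=haps))
        al = [("A", "B"), ("A", "b"), ("a", "B"), ("a", "b")]
        pairs = np.empty((n, 2), dtype=object)
        for i in range(n):
            h1, h2 = al[idx1[i]], al[idx2[i]]
            pairs[i, 0] = tuple(sorted((h1[0], h2[0])))
            pairs[i, 1] = tuple(sorted((h1[1], h2[1])))
        gm = tp.from_allele_pairs(pairs, ["s1", "s2"])
        lay = tp.solve_layout(tp.encode_all(gm))
        devs = [abs(tp.het_mid_deviation(lay, j)) for j in range(2)]
        # HWE reference spread at the same size
        null = []
        for s in range(10):
            gm0, _ = tp.simulate_blocks(tp.SimConfig(
                n=n, seed=100 + s, block_sizes=[2], maf=0.4, dprime_within=0.8))
            l0 = tp.solve_layout(tp.encode_all(gm0))
            null.append(max(abs(tp.het_mid_deviation(l0, j)) for j in range(2)))
        assert max(devs) > max(null)

    def test_missing_genotype_class_raises(self):
        pairs = np.empty((4, 2), dtype=object)
        for i in range(4):
            pairs[i, 0] = GENO_LABELS[0] if i % 2 else GENO_LABELS[1]
            pairs[i, 1] = GENO_LABELS[i % 3]
        gm = tp.from_allele_pairs(pairs, ["s1", "s2"])
        lay = tp.solve_layout(tp.encode_all(gm))
        with pytest.raises(ValueError):
            tp.het_mid_deviation(lay, 0)


class TestPhenotypeAxis:
    def test_phenotype_axis_fit_by_same_criterion(self):
        cfg = tp.SimConfig(n=300, seed=17, block_sizes=[2], maf=0.4,
                           dprime_within=0.9)
        gm, truth = tp.simulate_blocks(cfg)
        # risk allele at locus 0 raises case probability
        rng = np.random.default_rng(1)
        dose = np.array([(gm.allele_pair(i, 0).count("B")) for i in range(gm.n)])
        labels = np.where(rng.random(gm.n) < 0.2 + 0.3 * dose, "case", "ctrl")
        gm2 = tp.attach_phenotype(gm, labels, tp.CATEGORICAL)
        lay = tp.solve_layout(tp.encode_all(gm2))
        # the phenotype axis participates: nonzero scale, finite coords
        assert np.abs(lay.gamma[-1]).max() > 0
        bf = brute_force_layout(tp.encode_all(gm2), n_starts=4, seed=2)
        assert lay.objective <= bf + 1e-6 * max(bf, 1.0)

    def test_quantitative_axis_standardized(self):
        gm, _ = tp.simulate_blocks(tp.SimConfig(n=200, seed=19,
                                                block_sizes=[2], maf=0.4,
                                                dprime_within=0.9))
        rng = np.random.default_rng(4)
        trait = rng.standard_normal(gm.n) * 50 + 170
        gm2 = tp.attach_phenotype(gm, trait, tp.QUANTITATIVE)
        lay = tp.solve_layout(tp.encode_all(gm2))
        w = lay.weights[:, -1]
        y = lay.y[:, -1]
        mu = (w * y).sum() / w.sum()
        var = (w * (y - mu) ** 2).sum() / w.sum()
        # the axis dispersion equals |gamma| (unit-variance raw vector)
        np.testing.assert_allclose(np.sqrt(var), abs(lay.gamma[-1][0]),
                                   rtol=1e-9)


class TestExport:
    def test_layout_tsv_contains_header_and_rows(self, tmp_path, table1_gm):
        lay = tp.solve_layout(tp.encode_all(table1_gm))
        path = tmp_path / "layout.tsv"
        from textileplot.solver import export_layout_tsv
        export_layout_tsv(lay, path, ["snp1", "snp2"])
        text = path.read_text()
        assert "#eigenvalue" in text and "#objective" in text
        assert text.count("\naxis\t") == 6  # 2 axes x 3 categories
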