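"""Microsatellite statistics: diversity, differentiation, indices, QC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from matriflow.core import MISSING, GenotypeMatrix
from matriflow import msat
from conftest import make_genotypes


class TestExpectedHet:
    def test_two_equal_alleles_approaches_half(self):
        rows = [[(100, 102)]] * 50
        g = make_genotypes(rows, ["d"] * 50)
        he = msat.expected_het(g, "d").iloc[0]
        assert he == pytest.approx(0.5, abs=0.01)

    def test_unbiased_correction_small_sample(self):
        # 2 individuals, alleles {100,100,102,102}: p=q=0.5, n_genes=4
        rows = [[(100, 102)], [(100, 102)]]
        g = make_genotypes(rows, ["d", "d"])
        he = msat.expected_het(g, "d").iloc[0]
        assert he == pytest.approx(4 / 3 * 0.5)


class TestRarefiedAr:
    def test_equals_raw_count_at_full_sample(self):
        rows = [[(100, 102)], [(104, 104)], [(100, 106)]]
        g = make_genotypes(rows, ["d"] * 3)
        ar = msat.rarefied_ar(g, "d", 6).iloc[0]
        assert ar == pytest.approx(4.0)

    def test_matches_exhaustive_enumeration(self):
        """Hypergeometric rarefaction equals the mean allele count over
        all C(N, g) exact subsamples (brute-force oracle)."""
        alleles = [100, 100, 102, 104, 104, 106]  # N=6
        rows = [[(alleles[2 * i], alleles[2 * i + 1])] for i in range(3)]
        g = make_genotypes(rows, ["d"] * 3)
        g_sub = 4
        counts = []
        for combo in itertools.combinations(range(6), g_sub):
            counts.append(len({alleles[i] for i in combo}))
        assert msat.rarefied_ar(g, "d", g_sub).iloc[0] == pytest.approx(
            np.mean(counts)
        )

    def test_monotone_in_subsample_size(self):
        rng = np.random.default_rng(0)
        rows = [
            [(int(a), int(b))]
            for a, b in rng.integers(100, 110, size=(20, 2))
        ]
        g = make_genotypes(rows, ["d"] * 20)
        ars = [msat.rarefied_ar(g, "d", k).iloc[0] for k in (5, 10, 20, 40)]
        assert all(x <= y + 1e-12 for x, y in zip(ars, ars[1:]))

    def test_oversampling_errors(self):
        g = make_genotypes([[(100, 102)]], ["d"])
        with pytest.raises(ValueError):
            msat.rarefied_ar(g, "d", 3)


class TestFstAndFis:
    def test_fixed_difference_theta_one(self):
        rows = [[(100, 100)]] * 6 + [[(120, 120)]] * 6
        g = make_genotypes(rows, ["a"] * 6 + ["b"] * 6)
        fst, p = msat.pairwise_fst(g, "a", "b", n_perm=100, seed=1)
        assert fst == pytest.approx(1.0)
        assert p < 0.05

    def test_identical_demes_near_zero(self):
        rng = np.random.default_rng(1)
        rows = [
            [
                (int(a), int(b))
                for a, b in rng.integers(100, 104, size=(5, 2))
            ]
            for _ in range(30)
        ]
        g = make_genotypes(rows, ["a"] * 15 + ["b"] * 15)
        fst, p = msat.pairwise_fst(g, "a", "b", n_perm=100, seed=2)
        assert abs(fst) < 0.05
        assert p > 0.05

    def test_island_model_expectation(self, small_sim):
        """Realized W&C F_ST on generator data sits in the weak-structure
        band implied by the configured migration rates."""
        fst = msat.wc_theta(small_sim.genotypes)
        assert 0.0 < fst < 0.05

    def test_fis_zero_under_random_mating(self):
        rng = np.random.default_rng(3)
        pool = np.array([100, 102, 104, 106])
        freqs = np.array([0.4, 0.3, 0.2, 0.1])
        rows = [
            [
                tuple(rng.choice(pool, 2, p=freqs).astype(int))
                for _ in range(8)
            ]
            for _ in range(200)
        ]
        g = make_genotypes(rows, ["d"] * 200)
        assert abs(msat.fis(g, "d")) < 0.05

    def test_fis_positive_under_selfing(self):
        rng = np.random.default_rng(4)
        pool = np.array([100, 102, 104])
        rows = []
        for _ in range(120):
            row = []
            for _ in range(6):
                if rng.random() < 0.5:  # forced homozygote
                    a = int(rng.choice(pool))
                    row.append((a, a))
                else:
                    row.append(tuple(rng.choice(pool, 2).astype(int)))
            rows.append(row)
        g = make_genotypes(rows, ["d"] * 120)
        assert msat.fis(g, "d") > 0.2


class TestAmova:
    def test_identical_demes_fct_null(self):
        rng = np.random.default_rng(5)
        rows = [
            [
                tuple(rng.integers(100, 106, 2).astype(int))
                for _ in range(6)
            ]
            for _ in range(60)
        ]
        demes = [f"d{i % 6}" for i in range(60)]
        groups = {f"d{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        g = make_genotypes(rows, demes)
        res = msat.amova(g, groups, n_perm=100, seed=6)
        assert abs(res.f_ct) < 0.05
        assert res.p_ct > 0.05

    def test_group_separation_detected(self):
        rng = np.random.default_rng(7)
        rows = []
        demes = []
        for i in range(60):
            shift = 0 if i < 30 else 20  # the two groups use shifted alleles
            rows.append(
                [
                    tuple((rng.integers(100, 104, 2) + shift).astype(int))
                    for _ in range(6)
                ]
            )
            demes.append(f"d{i % 2}" if i < 30 else f"d{2 + i % 2}")
        groups = {"d0": "g1", "d1": "g1", "d2": "g2", "d3": "g2"}
        g = make_genotypes(rows, demes)
        res = msat.amova(g, groups, n_perm=100, seed=8)
        assert res.f_ct > 0.15
        assert res.p_ct < 0.2  # only 3 distinguishable deme permutations

    def test_variance_components_match_hand_computation(self):
        """One-locus haploid-style check against the textbook sums of
        squares computed directly from allele identity."""
        rows = [
            [(1, 1)], [(1, 2)],     # deme a (group g1)
            [(2, 2)], [(2, 2)],     # deme b (group g1)
            [(3, 3)], [(3, 4)],     # deme c (group g2)
            [(4, 4)], [(3, 4)],     # deme d (group g2)
        ]
        demes = ["a", "a", "b", "b", "c", "c", "d", "d"]
        groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        g = make_genotypes(rows, demes)
        res = msat.amova(g, groups, n_perm=50, seed=9)
        # hand computation of the same decomposition
        alleles = np.array([a for r in rows for a in r[0]])
        deme_of = np.repeat(np.arange(4), 4)
        grp_of = np.repeat(np.arange(2), 8)

        def ssd(idx_sets):
            s = 0.0
            for idx in idx_sets:
                sub = alleles[idx]
                nn = len(sub)
                d = sum(
                    sub[i] != sub[j]
                    for i in range(nn)
                    for j in range(i + 1, nn)
                )
                s += d / nn
            return s

        N, D, G = 16, 4, 2
        ssd_t = ssd([np.arange(N)])
        ssd_wg = ssd([np.where(grp_of == k)[0] for k in range(2)])
        ssd_wd = ssd([np.where(deme_of == k)[0] for k in range(4)])
        ms_wd = ssd_wd / (N - D)
        ms_ap = (ssd_wg - ssd_wd) / (D - G)
        ms_ag = (ssd_t - ssd_wg) / (G - 1)
        sig_c = ms_wd
        sig_b = (ms_ap - sig_c) / 4.0     # balanced: n' = 4
        sig_a = (ms_ag - sig_c - 4.0 * sig_b) / 8.0
        f_ct_hand = sig_a / (sig_a + sig_b + sig_c)
        assert res.f_ct == pytest.approx(f_ct_hand, abs=1e-9)


class TestIndividualIndices:
    def test_ir_sign_for_rare_allele_heterozygote(self):
        # individual het at every locus with globally rare alleles -> IR < 0
        rows = [[(100, 102)] * 4 for _ in range(20)]
        rows.append([(104, 106)] * 4)  # rare-allele carrier
        g = make_genotypes(rows, ["d"] * 21)
        ind = msat.individual_indices(g)
        assert ind.iloc[-1]["IR"] < 0

    def test_fully_homozygous_extremes(self):
        rows = [[(100, 102)] * 3 for _ in range(10)]
        rows.append([(100, 100)] * 3)
        g = make_genotypes(rows, ["d"] * 11)
        ind = msat.individual_indices(g)
        assert ind.iloc[-1]["HL"] == pytest.approx(1.0)
        assert ind.iloc[-1]["IR"] > 0
        assert (ind.iloc[:10]["HL"] == 0).all()

    def test_hl_closed_form_mixed_individual(self):
        # per-locus expected heterozygosities E1, E2; homozygous at locus 1
        # only -> HL = E1/(E1+E2)
        rows = [
            [(1, 1), (1, 2)],
            [(1, 2), (3, 4)],
            [(2, 2), (5, 6)],
            [(1, 2), (7, 8)],
        ]
        g = make_genotypes(rows, ["d"] * 4)
        he = []
        for l in range(2):
            cnt = g.allele_counts(l)
            n = sum(cnt.values())
            he.append(1 - sum((c / n) ** 2 for c in cnt.values()))
        ind = msat.individual_indices(g)
        assert ind.iloc[0]["HL"] == pytest.approx(he[0] / (he[0] + he[1]))

    def test_deme_specific_frequencies_matter(self):
        rows_a = [[(100, 100)] for _ in range(10)]
        rows_b = [[(120, 122)] for _ in range(10)]
        g1 = make_genotypes(rows_a + rows_b, ["a"] * 10 + ["b"] * 10)
        g2 = make_genotypes(rows_a + rows_b, ["a"] * 20)
        i1 = msat.individual_indices(g1)["IR"].to_numpy()
        i2 = msat.individual_indices(g2)["IR"].to_numpy()
        assert not np.allclose(i1, i2, equal_nan=True)

    def test_uniform_frequencies_rank_by_homozygote_count(self):
        """With all alleles equally frequent HL must order individuals
        exactly as their raw homozygous-locus count."""
        rng = np.random.default_rng(10)
        # construct uniform allele usage: rotate allele pairs
        rows = []
        for i in range(12):
            row = []
            for l in range(6):
                if (i + l) % 3 == 0:
                    a = 100 + 2 * ((i + l) % 4)
                    row.append((a, a))
                else:
                    a = 100 + 2 * ((i + l) % 4)
                    b = 100 + 2 * ((i + l + 1) % 4)
                    row.append((a, b))
            rows.append(row)
        g = make_genotypes(rows, ["d"] * 12)
        ind = msat.individual_indices(g)
        hom_counts = [
            sum(a == b for a, b in g.genotypes[i]) for i in range(12)
        ]
        order_hl = np.argsort(ind["HL"].to_numpy())
        order_cnt = np.argsort(np.array(hom_counts), kind="stable")
        assert (
            np.array(hom_counts)[order_hl]
            == np.sort(np.array(hom_counts))
        ).all()

    def test_undertyped_individual_excluded(self):
        rows = [[(100, 102)] * 4 for _ in range(5)]
        miss = [[(MISSING, MISSING)] * 3 + [(100, 102)]]
        g = make_genotypes(rows + miss, ["d"] * 6)
        ind = msat.individual_indices(g, min_typed=0.5)
        assert np.isnan(ind.iloc[-1]["IR"])


class TestRirRhl:
    def test_degenerate_table_warns(self):
        df = pd.DataFrame(
            {
                "mean_IR": [0.1] * 5,
                "mean_HL": [0.3] * 5,
                "F_IS": [0.15] * 5,
            }
        )
        with pytest.warns(UserWarning):
            out = msat.rir_rhl_diagnostic(df)
        assert np.isnan(out["R_IR"])

    def test_correlated_table_recovers_coefficients(self):
        rng = np.random.default_rng(11)
        fis = rng.uniform(0.05, 0.3, 9)
        df = pd.DataFrame(
            {
                "F_IS": fis,
                "mean_IR": fis * 0.9 + rng.normal(0, 0.01, 9),
                "mean_HL": fis * 0.8 + rng.normal(0, 0.03, 9),
            }
        )
        out = msat.rir_rhl_diagnostic(df)
        assert out["R_IR"] > 0.9
        assert out["R_HL"] > 0.5


class TestNullAlleleEM:
    def simulate_locus(self, rng, n, freqs, null_freq):
        alleles = list(range(len(freqs)))
        p = np.array(list(freqs) + [null_freq])
        p = p / p.sum()
        rows = []
        for _ in range(n):
            a, b = rng.choice(len(p), 2, p=p)
            null_a, null_b = a == len(freqs), b == len(freqs)
            if null_a and null_b:
                rows.append([(MISSING, MISSING)])
            elif null_a:
                rows.append([(100 + 2 * b, 100 + 2 * b)])
            elif null_b:
                rows.append([(100 + 2 * a, 100 + 2 * a)])
            else:
                rows.append([(100 + 2 * a, 100 + 2 * b)])
        return make_genotypes(rows, ["d"] * n)

    def test_no_nulls_estimates_near_zero(self):
        rng = np.random.default_rng(12)
        g = self.simulate_locus(rng, 300, [0.4, 0.3, 0.2, 0.1], 0.0)
        assert msat.null_allele_em(g, 0) < 0.03

    def test_recovers_simulated_null_frequency(self):
        rng = np.random.default_rng(13)
        est = []
        for rep in range(5):
            g = self.simulate_locus(rng, 200, [0.35, 0.3, 0.2], 0.15)
            est.append(msat.null_allele_em(g, 0, include_missing=True))
        assert abs(np.mean(est) - 0.15) < 0.05

    def test_monomorphic_returns_zero(self):
        g = make_genotypes([[(100, 100)]] * 20, ["d"] * 20)
        assert msat.null_allele_em(g, 0) == 0.0

    def test_study_scale_loci_below_threshold(self, study_sim):
        g = study_sim.genotypes
        ests = [msat.null_allele_em(g, l) for l in range(g.n_loci)]
        assert all(e < 0.20 for e in ests)


class TestEvanno:
    def test_linear_likelihood_gives_zero(self):
        K = np.arange(1, 7)
        L = pd.DataFrame(
            {r: -100 + 5.0 * K + 0.01 * r for r in range(3)}, index=K
        )
        dk = msat.evanno_delta_k(L)
        assert np.allclose(dk.values, 0.0)

    def test_known_second_difference(self):
        K = np.arange(1, 4)
        reps = {}
        rng = np.random.default_rng(14)
        for r in range(4):
            noise = rng.normal(0, 1.0, 3)
            reps[r] = np.array([-200.0, -120.0, -115.0]) + noise
        L = pd.DataFrame(reps, index=K)
        dk = msat.evanno_delta_k(L)
        expect = np.abs(
            L.loc[3] - 2 * L.loc[2] + L.loc[1]
        ).mean() / L.loc[2].std(ddof=1)
        assert dk[2] == pytest.approx(expect)

    def test_constant_replicates_error(self):
        L = pd.DataFrame({0: [1.0, 2.0, 3.0], 1: [1.0, 2.0, 3.0]},
                         index=[1, 2, 3])
        with pytest.raises(ZeroDivisionError):
            msat.evanno_delta_k(L)


class TestFdr:
    def test_single_test_unchanged(self):
        _, a = msat.fdr_correct([0.04], alpha=0.05)
        assert a == pytest.approx(0.05)

    def test_harmonic_sum_k10(self):
        _, a = msat.fdr_correct([0.01] * 10, alpha=0.05)
        assert a == pytest.approx(0.05 / sum(1 / i for i in range(1, 11)))
        assert a == pytest.approx(0.01707, abs=1e-4)

    def test_monotone_with_uncorrected(self):
        p = np.array([0.001, 0.02, 0.2, 0.9, 1.0])
        rej, a = msat.fdr_correct(p, alpha=0.05)
        assert set(np.where(rej)[0]) <= set(np.where(p <= 0.05)[0])

    def test_all_ones_nothing_significant(self):
        rej, _ = msat.fdr_correct([1.0] * 5)
        assert not rej.any()


class TestMantel:
    def test_identical_matrices_perfect_r(self):
        rng = np.random.default_rng(15)
        X = rng.random((6, 2))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        r, p = msat.mantel(D, D, n_perm=999, seed=1)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_exact_enumeration_on_3x3(self):
        """With 3 taxa all 6 permutations are enumerated; the p-value is
        an exact multiple of 1/6."""
        m1 = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        m2 = np.array([[0, 1.1, 2.2], [1.1, 0, 2.9], [2.2, 2.9, 0]])
        r, p = msat.mantel(m1, m2, n_perm=999)
        assert any(abs(p - k / 6) < 1e-12 for k in range(1, 7))
        assert p == pytest.approx(1 / 6)  # best alignment is the identity

    def test_independent_matrices_uniform_p(self):
        rng = np.random.default_rng(16)
        pvals = []
        for _ in range(100):
            a = rng.random((5, 5))
            b = rng.random((5, 5))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            b = (b + b.T) / 2
            np.fill_diagonal(b, 0)
            _, p = msat.mantel(a, b, n_perm=119, seed=int(rng.integers(1e6)))
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_against_reference_implementation(self):
        """Cross-check r against scikit-bio's Mantel on a random pair."""
        from skbio.stats.distance import DistanceMatrix, mantel as skmantel

        rng = np.random.default_rng(17)
        X = rng.random((7, 2))
        Y = X + rng.normal(0, 0.2, X.shape)
        d1 = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        d2 = np.linalg.norm(Y[:, None] - Y[None, :], axis=2)
        r_ours, _ = msat.mantel(d1, d2, n_perm=99, seed=0)
        r_ref, _, _ = skmantel(
            DistanceMatrix(d1), DistanceMatrix(d2), permutations=99
        )
        assert r_ours == pytest.approx(float(r_ref), abs=1e-9)
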