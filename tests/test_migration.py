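"""Structured-coalescent sampler: moves, likelihood, posterior, Nem."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from matriflow.migration import (
    ChainConfig,
    ChainDiagnosticError,
    Genealogy,
    LadderModel,
    compare_models,
    effective_migrants,
    genealogy_log_prior,
    rethread_lineage,
    resimulate_above,
    sample_posterior,
    scale_genealogy,
    simulate_genealogy,
    tree_loglik,
)
from matriflow.simulate import simulate_genotypes


def validate_genealogy(gen):
    """Structural audit: single root, binary nodes, consistent times and
    migration paths (child's arrival deme equals parent's deme)."""
    n = gen.n_leaves
    parent, time = gen.parent, gen.time
    roots = [x for x in range(2 * n - 1) if parent[x] < 0]
    assert len(roots) == 1
    ch = Counter(int(p) for p in parent if p >= 0)
    for u in range(n, 2 * n - 1):
        assert ch.get(u, 0) == 2
    for u in range(2 * n - 1):
        pu = parent[u]
        if pu < 0:
            continue
        assert time[pu] > time[u] - 1e-12
        d = int(gen.node_deme[u])
        for (t, i, j) in gen.mig.get(u, []):
            assert i == d
            assert time[u] - 1e-12 <= t <= time[pu] + 1e-12
            d = j
        assert d == int(gen.node_deme[pu])


class TestLadder:
    def test_rows_are_distributions(self):
        lad = LadderModel(10, 20)
        for t in (0.01, 1.0, 50.0):
            P = lad.transition(t)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert (P >= 0).all()

    def test_long_time_limit_uniform(self):
        lad = LadderModel(1, 8)
        P = lad.transition(1e6)
        assert np.allclose(P, 1.0 / 8, atol=1e-6)

    def test_short_time_near_identity(self):
        lad = LadderModel(1, 10)
        assert np.allclose(lad.transition(1e-8), np.eye(10), atol=1e-6)


class TestTreeLoglik:
    def hand_tree(self, t1, t2):
        # ((0,1) at t1, 2) at t2: three leaves, one deme
        parent = np.array([3, 3, 4, 4, -1])
        time = np.array([0.0, 0.0, 0.0, t1, t2])
        return Genealogy(parent, time, 3, 1, np.zeros(5, dtype=int), {})

    def test_matches_bruteforce_state_sum(self):
        """Pruning equals the explicit sum over all internal-node states."""
        lad = LadderModel(1, 6)
        states = np.array([1, 2, 4])
        gen = self.hand_tree(0.4, 1.3)
        got = tree_loglik(gen, states, lad)
        P1 = lad.transition(0.4)
        P2 = lad.transition(1.3)
        P12 = lad.transition(1.3 - 0.4)
        S = 6
        total = 0.0
        for root in range(S):
            for mid in range(S):
                total += (
                    (1 / S)
                    * P12[root, mid]
                    * P1[mid, states[0]]
                    * P1[mid, states[1]]
                    * P2[root, states[2]]
                )
        assert got == pytest.approx(np.log(total), abs=1e-9)

    def test_missing_leaf_marginalised(self):
        lad = LadderModel(1, 6)
        gen = self.hand_tree(0.4, 1.3)
        full = [
            np.exp(tree_loglik(gen, np.array([1, a, 4]), lad))
            for a in range(6)
        ]
        got = tree_loglik(gen, np.array([1, -1, 4]), lad)
        assert got == pytest.approx(np.log(sum(full)), abs=1e-9)


class TestMoves:
    @pytest.fixture()
    def setting(self):
        rng = np.random.default_rng(5)
        theta = np.array([3.0, 5.0, 2.0])
        M = np.array(
            [[0.0, 2.0, 1.0], [3.0, 0.0, 0.5], [1.0, 2.0, 0.0]]
        )
        deme_of_leaf = np.array([0] * 5 + [1] * 5 + [2] * 5)
        return rng, theta, M, deme_of_leaf

    def test_all_moves_keep_genealogies_valid(self, setting):
        rng, theta, M, dl = setting
        gen = simulate_genealogy(dl, theta, M, rng)
        validate_genealogy(gen)
        for it in range(800):
            u = rng.random()
            if u < 0.3:
                cand = resimulate_above(
                    gen, rng.uniform(0, gen.tmrca), theta, M, rng
                )
            elif u < 0.5:
                cand = scale_genealogy(gen, float(np.exp(rng.uniform(-0.3, 0.3))))
            else:
                v = int(rng.integers(0, 2 * gen.n_leaves - 1))
                if v == gen.root:
                    continue
                cand = rethread_lineage(gen, v, theta, M, rng)
            if cand is not None:
                validate_genealogy(cand)
                gen = cand

    def test_prior_preserved_by_rethreading(self, setting):
        """A flat-likelihood chain driven by re-threading must keep the
        structured-coalescent prior (checked on TMRCA)."""
        rng, theta, M, dl = setting
        gen = simulate_genealogy(dl, theta, M, rng)
        chain = []
        for it in range(3000):
            v = int(rng.integers(0, 2 * gen.n_leaves - 1))
            if v != gen.root:
                cand = rethread_lineage(gen, v, theta, M, rng)
                if cand is not None:
                    gen = cand
            if it % 15 == 0:
                chain.append(gen.tmrca)
        direct = [
            simulate_genealogy(dl, theta, M, rng).tmrca for _ in range(300)
        ]
        assert stats.ks_2samp(chain[20:], direct).pvalue > 0.005

    def test_log_prior_matches_replay(self, setting):
        """The cached-exposure prior equals a direct replay of the event
        history at different parameter values."""
        rng, theta, M, dl = setting
        gen = simulate_genealogy(dl, theta, M, rng)
        theta2 = theta * 1.7
        M2 = M * 0.6
        lp_cached = genealogy_log_prior(gen, theta2, M2)
        # replay: recompute exposures from the raw tree + migration lists
        gen2 = Genealogy(
            gen.parent.copy(),
            gen.time.copy(),
            gen.n_leaves,
            gen.k,
            gen.node_deme.copy(),
            {u: list(v) for u, v in gen.mig.items()},
        )
        lp_replay = genealogy_log_prior(gen2, theta2, M2)
        assert lp_cached == pytest.approx(lp_replay, abs=1e-8)

    def test_scale_move_scales_exposures(self, setting):
        rng, theta, M, dl = setting
        gen = simulate_genealogy(dl, theta, M, rng)
        gen.compute_stats()
        s = 1.7
        scaled = scale_genealogy(gen, s)
        pt, lt, nc, nm = gen.stats
        pt2, lt2, nc2, nm2 = scaled.stats
        assert np.allclose(pt2, pt * s)
        assert np.allclose(lt2, lt * s)
        assert np.array_equal(nc, nc2)
        assert np.array_equal(nm, nm2)


class TestPosterior:
    def test_prior_only_run_recovers_uniform_marginals(self):
        """With likelihood = 1 the chain must sample the uniform priors
        of theta and M (detailed-balance check; prior ranges reduced so
        migration histories stay below the event cap)."""
        g = simulate_genotypes([3.0, 3.0], np.array([[0, 5.0], [5.0, 0]]),
                               [4, 4], n_loci=2, seed=1)
        cfg = ChainConfig(steps=500, thin=5, replicates=1,
                          burnin_fraction=0.2, strict=False,
                          p_global_redraw=0.25, theta_max=50.0, m_max=20.0)
        run = sample_posterior(g, "island", cfg, seed=3, flat_likelihood=True)
        th = run.theta_trace[:, 0]
        ks_t = stats.kstest(th / 50.0, "uniform")
        m = run.m_trace[:, 0, 1]
        ks_m = stats.kstest(m / 20.0, "uniform")
        assert ks_t.pvalue > 0.001
        assert ks_m.pvalue > 0.001

    def test_two_tip_theta_posterior_matches_quadrature(self):
        """Two gene copies, one deme, one locus: the sampler's theta
        posterior must match direct numerical integration of
        p(theta | D) over the coalescence time."""
        from scipy.integrate import quad

        lad = LadderModel(90, 110)
        a1, a2 = 100, 101
        rows = [[(a1, a2)]]
        from conftest import make_genotypes

        g = make_genotypes(rows, ["d"])
        cfg = ChainConfig(
            steps=2500, thin=4, replicates=2,
            burnin_fraction=0.2, ladder_buffer=10, strict=False,
        )
        run = sample_posterior(g, "panmixia", cfg, seed=7)

        s1, s2 = lad.state_of(a1), lad.state_of(a2)

        def lik_t(t):
            P = lad.transition(t)
            return float(np.mean(P[:, s1] * P[:, s2]))

        def marg(theta):
            val, _ = quad(
                lambda t: lik_t(t) * (2 / theta) * np.exp(-2 * t / theta),
                0, 50 * theta, limit=200,
            )
            return val

        grid = np.linspace(0.5, 199.5, 120)
        dens = np.array([marg(th) for th in grid])
        dens /= np.trapezoid(dens, grid)
        mean_quad = float(np.trapezoid(grid * dens, grid))
        mean_mcmc = float(run.theta_trace.mean())
        assert mean_mcmc == pytest.approx(mean_quad, rel=0.15)

    def test_single_deme_theta_recovery(self):
        """Posterior intervals bracket the generating theta in most
        single-deme replicates."""
        cfg = ChainConfig(steps=400, thin=10, replicates=1,
                          burnin_fraction=2.0, strict=False)
        cover = 0
        reps = 5
        for s in range(reps):
            g = simulate_genotypes([5.0], None, [10], n_loci=5, seed=500 + s)
            run = sample_posterior(g, "panmixia", cfg, seed=600 + s)
            lo, hi = run.theta_ci[0]
            cover += lo <= 5.0 <= hi
        assert cover >= reps - 1

    def test_mixing_diagnostic_raises(self):
        g = simulate_genotypes([5.0], None, [8], n_loci=3, seed=9)
        cfg = ChainConfig(steps=30, thin=2, replicates=1, min_ess=1e9)
        with pytest.raises(ChainDiagnosticError):
            sample_posterior(g, "panmixia", cfg, seed=1)

    def test_small_deme_rejected(self):
        g = simulate_genotypes([2.0, 2.0], np.array([[0, 5.0], [5.0, 0]]),
                               [6, 3], n_loci=2, seed=10)
        with pytest.raises(ValueError):
            sample_posterior(g, "island", ChainConfig(steps=10, thin=1))


class TestModelComparison:
    def test_identical_runs_zero_bayes_factor(self):
        g = simulate_genotypes([4.0], None, [8], n_loci=3, seed=11)
        cfg = ChainConfig(steps=80, thin=4, replicates=1,
                          burnin_fraction=0.3, strict=False)
        run = sample_posterior(g, "panmixia", cfg, seed=12)
        out = compare_models(run, run)
        assert out["log_bayes_factor"] == 0.0
        assert out["favoured"] == "indecisive"


class TestEffectiveMigrants:
    def test_zero_migration(self):
        nem = effective_migrants(np.array([1.0, 2.0]), np.zeros((2, 2)))
        assert np.allclose(nem, 0)

    def test_table_inversion_case(self):
        # theta_C = 4.2 with M(A->C) = 19.667 gives Nem = 20.65
        theta = np.array([0.067, 0.067, 4.2])
        M = np.zeros((3, 3))
        M[0, 2] = 19.667
        nem = effective_migrants(theta, M)
        assert nem[0, 2] == pytest.approx(20.65, abs=0.01)

    def test_unit_case_and_shape(self):
        theta = np.array([4.0, 4.0])
        M = np.array([[0.0, 1.0], [1.0, 0.0]])
        nem = effective_migrants(theta, M)
        assert nem[1, 0] == pytest.approx(1.0)
        assert nem.shape == (2, 2)
        assert np.allclose(np.diag(nem), 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            effective_migrants(np.array([1.0]), np.zeros((2, 2)))
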