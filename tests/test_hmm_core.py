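import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from ulpcna.hmm_core import (
    CopyState,
    HyperParams,
    ModelParams,
    default_hyperparams,
    default_state_space,
    forward_backward,
    map_m_step,
    run_em,
    run_restarts,
    state_means,
    student_t_logpdf,
    transition_matrix,
    viterbi,
)
from ulpcna.normalize import LogRatioTrack
from ulpcna.bins_io import build_bin_grid


def _toy_track(values, chrom_size=None):
    values = np.asarray(values, dtype=float)
    grid = build_bin_grid({"chr1": len(values) * 1_000_000}, 1_000_000)
    return LogRatioTrack(grid=grid, l=values)


class TestStateSpace:
    def test_clonal_states(self):
        states = default_state_space(include_subclonal=False)
        assert [s.copies for s in states] == [1, 2, 3, 4, 5]
        assert not any(s.subclonal for s in states)

    def test_subclonal_extension(self):
        states = default_state_space(include_subclonal=True)
        assert len(states) == 7
        assert [s.copies for s in states if s.subclonal] == [1, 3]

    def test_labels(self):
        states = default_state_space(include_subclonal=False)
        assert [s.label for s in states] == ["HETD", "NEUT", "GAIN", "AMP", "HLAMP"]

    def test_invalid_subclonal_copies(self):
        with pytest.raises(ValueError):
            CopyState("bad", 4, subclonal=True)


class TestStateMeans:
    def test_pure_normal_all_zero(self):
        states = default_state_space(True)
        mu = state_means(1.0, 0.3, 2.0, states)
        assert np.allclose(mu, 0.0)

    def test_state_at_ploidy_is_zero(self):
        states = default_state_space(False)
        for phi in (2.0, 3.0, 4.0):
            mu = state_means(0.4, 0.0, phi, states)
            g = [s.copies for s in states].index(int(phi))
            assert mu[g] == pytest.approx(0.0, abs=1e-12)

    def test_half_tumor_gain(self):
        # n=0.5, c=3, phi=2: (2*0.5 + 0.5*3)/(2*0.5 + 0.5*2) = 2.5/2 = 1.25
        states = default_state_space(False)
        mu = state_means(0.5, 0.0, 2.0, states)
        assert mu[2] == pytest.approx(math.log2(1.25), abs=1e-12)

    def test_subclonal_mean_attenuated(self):
        states = default_state_space(True)
        mu = state_means(0.5, 0.4, 2.0, states)
        gain = [i for i, s in enumerate(states) if s.copies == 3 and not s.subclonal][0]
        gain_sc = [i for i, s in enumerate(states) if s.copies == 3 and s.subclonal][0]
        assert 0 < mu[gain_sc] < mu[gain]

    def test_strictly_increasing_in_copies(self):
        states = default_state_space(False)
        for n in (0.0, 0.3, 0.7):
            mu = state_means(n, 0.0, 2.4, states)
            assert (np.diff(mu) > 0).all()


class TestEmission:
    def test_mode_height_closed_form(self):
        nu, lam = 2.1, 25.0
        height = math.exp(student_t_logpdf(np.array([0.3]), 0.3, np.array([lam]), nu)[0])
        expected = (
            math.exp(gammaln((nu + 1) / 2) - gammaln(nu / 2))
            * math.sqrt(lam / (math.pi * nu))
        )
        assert height == pytest.approx(expected, rel=1e-12)

    def test_symmetry(self):
        lp = student_t_logpdf(np.array([0.1, 0.5]), 0.3, np.array([10.0]), 2.1)
        assert lp[0] == pytest.approx(lp[1], rel=1e-12)

    def test_normalization_by_quadrature(self):
        nu, lam, mu = 2.1, 30.0, -0.2
        integral, _ = quad(
            lambda x: math.exp(student_t_logpdf(np.array([x]), mu, np.array([lam]), nu)[0]),
            -np.inf, np.inf,
        )
        assert integral == pytest.approx(1.0, abs=1e-6)


class TestTransitionMatrix:
    def test_paper_defaults(self):
        A = transition_matrix(7, 0.99999)
        assert np.allclose(np.diag(A), 0.99999)
        off = A[0, 1]
        assert off == pytest.approx(1e-5 / 6, rel=1e-9)

    def test_two_state_half(self):
        assert np.allclose(transition_matrix(2, 0.5), 0.5)

    @pytest.mark.parametrize("k,e", [(2, 0.9), (5, 0.99999), (7, 0.5)])
    def test_rows_sum_to_one(self, k, e):
        assert np.allclose(transition_matrix(k, e).sum(axis=1), 1.0)


class TestHyperParams:
    def test_precision_prior_formula(self):
        rng = np.random.default_rng(0)
        l = rng.normal(0, 0.1, 20_000)
        states = default_state_space(True)
        hyper = default_hyperparams(l, states)
        sd = l.std()
        assert hyper.lambda_scale == pytest.approx((sd / math.sqrt(7)) ** -1, rel=1e-12)
        assert hyper.lambda_scale == pytest.approx(26.46, rel=0.02)

    def test_constants(self):
        hyper = default_hyperparams(np.array([0.0, 0.1, -0.1, 0.2]), default_state_space(True))
        assert hyper.lambda_shape == 3.0
        assert hyper.nu == 2.1
        assert hyper.e == 0.99999

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            default_hyperparams(np.zeros(100), default_state_space(True))


def _brute_force_loglik(log_b, A, pi):
    T, K = log_b.shape
    total = -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = math.log(pi[path[0]]) + log_b[0, path[0]]
        for t in range(1, T):
            lp += math.log(A[path[t - 1], path[t]]) + log_b[t, path[t]]
        total = np.logaddexp(total, lp)
    return total


def _brute_force_viterbi(log_b, A, pi):
    T, K = log_b.shape
    best, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        lp = math.log(pi[path[0]]) + log_b[0, path[0]]
        for t in range(1, T):
            lp += math.log(A[path[t - 1], path[t]]) + log_b[t, path[t]]
        if lp > best:  # strict: first (lexicographically smallest) max kept
            best, best_path = lp, path
    return np.array(best_path), best


class TestForwardBackward:
    def test_single_step_posterior(self):
        log_b = np.log(np.array([[0.2, 0.6]]))
        A = transition_matrix(2, 0.9)
        pi = np.array([0.5, 0.5])
        gamma, ll = forward_backward(log_b, A, pi)
        expected = np.array([0.1, 0.3]) / 0.4
        assert np.allclose(gamma[0], expected)
        assert ll == pytest.approx(math.log(0.4))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        T, K = rng.integers(2, 9), rng.integers(2, 4)
        log_b = rng.normal(0, 2, (T, K))
        A = rng.dirichlet(np.ones(K) * 2, size=K)
        pi = rng.dirichlet(np.ones(K))
        gamma, ll = forward_backward(log_b, A, pi)
        assert ll == pytest.approx(_brute_force_loglik(log_b, A, pi), abs=1e-10)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_emissions_uniform_posterior(self):
        log_b = np.zeros((6, 3))
        A = transition_matrix(3, 0.8)
        pi = np.full(3, 1 / 3)
        gamma, _ = forward_backward(log_b, A, pi)
        assert np.allclose(gamma, 1 / 3)

    def test_emission_scaling_invariance(self):
        rng = np.random.default_rng(7)
        log_b = rng.normal(0, 1, (50, 4))
        A = transition_matrix(4, 0.95)
        pi = np.full(4, 0.25)
        g1, ll1 = forward_backward(log_b, A, pi)
        g2, ll2 = forward_backward(log_b + 7.5, A, pi)
        assert np.allclose(g1, g2, atol=1e-12)
        assert ll2 - ll1 == pytest.approx(7.5 * 50, rel=1e-12)

    def test_all_impossible_bin_errors(self):
        log_b = np.zeros((3, 2))
        log_b[1] = -np.inf
        with pytest.raises(ValueError):
            forward_backward(log_b, transition_matrix(2, 0.9), np.array([0.5, 0.5]))


class TestViterbi:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_argmax(self, seed):
        rng = np.random.default_rng(100 + seed)
        T, K = rng.integers(2, 9), rng.integers(2, 4)
        log_b = rng.normal(0, 2, (T, K))
        A = rng.dirichlet(np.ones(K) * 2, size=K)
        pi = rng.dirichlet(np.ones(K))
        path = viterbi(log_b, A, pi)
        expected, _ = _brute_force_viterbi(log_b, A, pi)
        assert (path == expected).all()

    def test_near_uniform_transitions_give_pointwise_argmax(self):
        rng = np.random.default_rng(8)
        log_b = rng.normal(0, 3, (30, 3))
        A = transition_matrix(3, 1 / 3 + 1e-9)
        pi = np.full(3, 1 / 3)
        path = viterbi(log_b, A, pi)
        assert (path == log_b.argmax(axis=1)).all()

    def test_sticky_limit_constant_path(self):
        rng = np.random.default_rng(9)
        log_b = rng.normal(0, 0.1, (40, 3))
        A = transition_matrix(3, 1 - 1e-12)
        pi = np.full(3, 1 / 3)
        path = viterbi(log_b, A, pi)
        assert len(set(path.tolist())) == 1
        assert path[0] == log_b.sum(axis=0).argmax()

    def test_scaling_invariance(self):
        rng = np.random.default_rng(10)
        log_b = rng.normal(0, 1, (25, 4))
        A = transition_matrix(4, 0.99)
        pi = np.full(4, 0.25)
        assert (viterbi(log_b, A, pi) == viterbi(log_b - 3.2, A, pi)).all()


class TestMStep:
    def _setup(self, seed=0, n_bins=2000, n=0.6, phi=2.0):
        rng = np.random.default_rng(seed)
        states = default_state_space(False)
        true_path = np.zeros(n_bins, dtype=int) + 1
        true_path[200:500] = 2
        true_path[900:1200] = 0
        mu = state_means(n, 0.0, phi, states)
        l = mu[true_path] + rng.normal(0, 0.05, n_bins)
        hyper = default_hyperparams(l, states)
        return states, l, hyper, true_path

    def test_lambda_update_matches_numerical_map(self):
        states, l, hyper, true_path = self._setup()
        track = _toy_track(l)
        em = run_em(track, 0.55, 2.0, hyper=hyper, states=states,
                    exclude_chr19=False, max_iter=60, abs_tol=1e-6, rel_tol=0.0)
        p = em.params
        mu = state_means(p.n, p.s, p.phi, states)
        gamma = em.gamma
        data = track.l[em.decode_mask]
        # independent oracle: per-state numerical maximization of the
        # posterior-weighted Student-t likelihood plus the Gamma prior
        for g in range(len(states)):
            if gamma[:, g].sum() < 50:
                continue
            def neg(lam):
                lp = student_t_logpdf(data, mu[g], np.array([lam]), hyper.nu)
                prior = (hyper.lambda_shape - 1) * math.log(lam) - lam / hyper.lambda_scale
                return -(gamma[:, g] @ lp + prior)
            res = minimize_scalar(neg, bounds=(1.0, 1e5), method="bounded",
                                  options={"xatol": 1e-6})
            assert p.lam[g] == pytest.approx(res.x, rel=1e-3)

    def test_self_consistency_at_generating_values(self):
        states, l, hyper, _ = self._setup(seed=1)
        track = _toy_track(l)
        em = run_em(track, 0.6, 2.0, hyper=hyper, states=states,
                    exclude_chr19=False, max_iter=80, abs_tol=1e-6, rel_tol=0.0)
        assert em.params.n == pytest.approx(0.6, abs=0.01)
        assert em.params.phi == pytest.approx(2.0, abs=0.05)

    def test_neutral_data_pushes_n_to_bound(self):
        rng = np.random.default_rng(2)
        states = default_state_space(False)
        l = rng.normal(0, 0.05, 1500)
        hyper = default_hyperparams(l, states)
        gamma = np.zeros((1500, 5))
        gamma[:, 1] = 1.0  # all mass on NEUT
        params = ModelParams(
            n=0.7, s=0.1, phi=2.0, lam=np.full(5, 400.0),
            A=transition_matrix(5, hyper.e), pi=np.full(5, 0.2),
        )
        updated = map_m_step(gamma, l, states, hyper, params)
        # no CNA signal: likelihood flat in n, phi pulled so mu_NEUT = 0
        assert abs(state_means(updated.n, 0.0, updated.phi, states)[1]) < 0.01


class TestRunEM:
    def test_monotone_objective(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            states = default_state_space(True)
            l = rng.normal(0, 0.1, 400) + np.repeat(
                rng.choice([-0.15, 0.0, 0.12], 8), 50
            )
            em = run_em(_toy_track(l), 0.7, 2.0, states=states, exclude_chr19=False)
            trace = np.array(em.loglik_trace)
            assert (np.diff(trace) > -1e-6).all()

    def test_gamma_rows_normalized(self):
        rng = np.random.default_rng(4)
        l = rng.normal(0, 0.1, 300)
        em = run_em(_toy_track(l), 0.6, 2.0, exclude_chr19=False)
        assert np.allclose(em.gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_chr19_excluded_from_training_retained_for_decoding(self):
        grid = build_bin_grid({"chr1": 150_000_000, "chr19": 50_000_000}, 1_000_000)
        rng = np.random.default_rng(5)
        l = LogRatioTrack(grid=grid, l=rng.normal(0, 0.1, grid.n_bins))
        em = run_em(l, 0.6, 2.0)
        chr19 = grid.chrom_mask("chr19")
        assert not (em.train_mask & chr19).any()
        assert (em.decode_mask & chr19).sum() == chr19.sum()
        assert em.gamma.shape[0] == em.decode_mask.sum()

    def test_too_few_bins_errors(self):
        l = _toy_track(np.zeros(50) + 0.01)
        with pytest.raises(ValueError):
            run_em(l, 0.6, 2.0, exclude_chr19=False)


class TestRestarts:
    def test_default_grid_size(self):
        rng = np.random.default_rng(6)
        l = _toy_track(rng.normal(0, 0.1, 200))
        results = run_restarts(l, exclude_chr19=False, max_iter=5)
        assert len(results) == 21
        assert {r.init for r in results} == {
            (n0, p0)
            for n0 in (0.35, 0.45, 0.50, 0.65, 0.75, 0.85, 0.95)
            for p0 in (2.0, 3.0, 4.0)
        }

    def test_serial_protocol_grid(self):
        rng = np.random.default_rng(7)
        l = _toy_track(rng.normal(0, 0.1, 200))
        results = run_restarts(l, phi0_grid=(2.0,), exclude_chr19=False, max_iter=5)
        assert len(results) == 7

    def test_best_f_deterministic(self):
        rng = np.random.default_rng(8)
        l = _toy_track(rng.normal(0, 0.1, 300))
        a = run_restarts(l, exclude_chr19=False, max_iter=10)
        b = run_restarts(l, exclude_chr19=False, max_iter=10)
        assert max(r.F for r in a) == max(r.F for r in b)
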