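"""Bayesian hidden Markov model for joint copy-number segmentation and
tumor-fraction / ploidy estimation from 1 Mb log2 copy ratios.

Model summary
-------------
Each bin t carries a hidden copy-number state ``G_t`` from a small set K
(clonal copies 1..5, optionally subclonal one-copy loss and gain).  The
observed log2 ratio ``l_t`` is Student's-t distributed around a state mean

    mu_g = log2( (2n + 2 s_g (1-n) + (1 - s_g)(1-n) c_g) / (2n + (1-n) phi) )

where ``n`` is the normal (non-tumor) cfDNA fraction, ``phi`` the average
tumor ploidy, ``c_g`` the state's integer copy number and ``s_g`` the
fraction of tumor not carrying the event (0 for clonal states, a shared
``s`` for subclonal states).  Transitions are stationary with a large
self-transition probability ``e``.  Parameters get conjugate-style priors
(Beta on n and s, Gamma on phi and on each precision lambda_g, Dirichlet on
pi) and are fit by EM with MAP M-steps; the EM objective ``F`` is the
observed-data log-likelihood plus the log prior.

Log base: state means are expressed in log base 2 so that they live on the
same scale as the input log2 ratios (a diploid bin at phi = 2 sits at 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import betaln, gammaln

from .normalize import LogRatioTrack

logger = logging.getLogger(__name__)

SELF_TRANSITION = 0.99999
STUDENT_T_DOF = 2.1            # fixed, not estimated
LAMBDA_SHAPE = 3.0             # Gamma shape of the precision prior

DEFAULT_N0_GRID = (0.35, 0.45, 0.50, 0.65, 0.75, 0.85, 0.95)
DEFAULT_PHI0_GRID = (2.0, 3.0, 4.0)

N_BOUNDS = (0.01, 0.99)
S_BOUNDS = (0.01, 0.99)
PHI_BOUNDS = (1.5, 5.0)

_COPY_LABELS = {1: "HETD", 2: "NEUT", 3: "GAIN", 4: "AMP", 5: "HLAMP"}


@dataclass(frozen=True)
class CopyState:
    label: str
    copies: int
    subclonal: bool = False

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copy number states must have at least one copy")
        if self.subclonal and self.copies not in (1, 3):
            raise ValueError("subclonal states are restricted to 1 or 3 copies")


def default_state_space(include_subclonal: bool = True) -> list[CopyState]:
    """Clonal copies {1..5}; optionally subclonal HETD_sc and GAIN_sc."""
    states = [CopyState(_COPY_LABELS[c], c) for c in (1, 2, 3, 4, 5)]
    if include_subclonal:
        states.append(CopyState("HETD_sc", 1, subclonal=True))
        states.append(CopyState("GAIN_sc", 3, subclonal=True))
    return states


@dataclass(frozen=True)
class HyperParams:
    """Prior hyperparameters; the defaults are uniform except the precision
    prior, whose Gamma scale tracks the sample's log-ratio spread."""

    n_alpha: float = 1.0
    n_beta: float = 1.0
    s_alpha: float = 1.0
    s_beta: float = 1.0
    phi_shape: float = 1.0
    phi_rate: float = 0.0          # 0 -> flat (improper) prior on ploidy
    lambda_shape: float = LAMBDA_SHAPE
    lambda_scale: float = 1.0      # Gamma *scale*; see default_hyperparams
    pi_delta: float = 1.0
    A_delta: float = 1.0
    e: float = SELF_TRANSITION
    nu: float = STUDENT_T_DOF

    def __post_init__(self) -> None:
        if not (0 < self.e < 1):
            raise ValueError("self-transition e must lie in (0, 1)")
        if self.nu <= 2:
            raise ValueError("degrees of freedom must exceed 2")


def default_hyperparams(l: np.ndarray | LogRatioTrack, states: Sequence[CopyState]) -> HyperParams:
    """Flat priors, with the precision prior scaled to the sample:
    lambda_g ~ Gamma(shape=3, scale=(sd(l)/sqrt(|K|))^-1)."""
    values = l.values() if isinstance(l, LogRatioTrack) else np.asarray(l, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least two valid bins to set hyperparameters")
    sd = float(np.std(values))
    if sd <= 0:
        raise ValueError("zero-variance log ratios; cannot set precision prior")
    return HyperParams(lambda_scale=math.sqrt(len(states)) / sd)


@dataclass
class ModelParams:
    n: float                   # normal (non-tumor) fraction
    s: float                   # fraction of tumor NOT carrying subclonal events
    phi: float                 # average tumor ploidy
    lam: np.ndarray            # per-state Student's-t precision
    A: np.ndarray              # transition matrix
    pi: np.ndarray             # initial state distribution

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.lam <= 0):
            raise ValueError("precisions must be positive")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")

    @property
    def tumor_fraction(self) -> float:
        return 1.0 - self.n


@dataclass
class EMResult:
    params: ModelParams
    F: float                         # complete-data log posterior at convergence
    gamma: np.ndarray                # posterior state probabilities on decode bins
    loglik_trace: list[float]
    iterations: int
    init: tuple[float, float]        # (n0, phi0)
    states: list[CopyState]
    hyper: HyperParams
    train_mask: np.ndarray
    decode_mask: np.ndarray
    converged: bool = False


# ---------------------------------------------------------------------------
# emission / transition primitives

def state_means(n: float, s: float, phi: float, states: Sequence[CopyState]) -> np.ndarray:
    """Mixture-model state means on the log2-ratio scale."""
    if not (0.0 <= n <= 1.0) or not (0.0 <= s <= 1.0):
        raise ValueError("n and s must lie in [0, 1]")
    if phi <= 0:
        raise ValueError("ploidy must be positive")
    den = 2.0 * n + (1.0 - n) * phi
    if den <= 0:
        raise ValueError("non-positive denominator in state means")
    c = np.array([st.copies for st in states], dtype=float)
    sg = np.array([s if st.subclonal else 0.0 for st in states])
    num = 2.0 * n + 2.0 * sg * (1.0 - n) + (1.0 - sg) * (1.0 - n) * c
    if np.any(num <= 0):
        raise ValueError("non-positive numerator in state means")
    return np.log2(num / den)


def student_t_logpdf(x: np.ndarray, mu: np.ndarray, lam: np.ndarray, nu: float) -> np.ndarray:
    """Log density of the three-parameter Student's t (precision form)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0) or nu <= 0:
        raise ValueError("precision and degrees of freedom must be positive")
    const = gammaln((nu + 1.0) / 2.0) - gammaln(nu / 2.0) + 0.5 * np.log(lam / (math.pi * nu))
    z2 = lam * (np.asarray(x, dtype=float) - mu) ** 2
    return const - (nu + 1.0) / 2.0 * np.log1p(z2 / nu)


def emission_logdensity(
    l: LogRatioTrack | np.ndarray,
    mu: np.ndarray,
    lam: np.ndarray,
    nu: float = STUDENT_T_DOF,
) -> np.ndarray:
    """T x |K| matrix of per-bin, per-state log emission densities."""
    values = l.values() if isinstance(l, LogRatioTrack) else np.asarray(l, dtype=float)
    return student_t_logpdf(values[:, None], mu[None, :], lam[None, :], nu)


def transition_matrix(k_size: int, e: float = SELF_TRANSITION) -> np.ndarray:
    """Stationary transitions: ``e`` on the diagonal, the remainder spread
    uniformly over the other states."""
    if k_size < 2:
        raise ValueError("need at least two states")
    off = (1.0 - e) / (k_size - 1)
    A = np.full((k_size, k_size), off)
    np.fill_diagonal(A, e)
    return A


# ---------------------------------------------------------------------------
# chain recursions (numba-accelerated when available)

def _fb_core(b: np.ndarray, A: np.ndarray, pi: np.ndarray):
    T, K = b.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)
    a = pi * b[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    At = A.T.copy()
    for t in range(1, T):
        a = b[t] * np.dot(At, alpha[t - 1])
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        v = np.dot(A, b[t + 1] * beta[t + 1])
        beta[t] = v / c[t + 1]
    gamma = alpha * beta
    for t in range(T):
        gamma[t] /= gamma[t].sum()
    return gamma, np.log(c).sum()


def _viterbi_core(log_b: np.ndarray, log_A: np.ndarray, log_pi: np.ndarray):
    T, K = log_b.shape
    delta = log_pi + log_b[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(K)
        for j in range(K):
            best = delta[0] + log_A[0, j]
            arg = 0
            for i in range(1, K):
                v = delta[i] + log_A[i, j]
                if v > best:  # strict: ties break toward the lowest index
                    best = v
                    arg = i
            new[j] = best + log_b[t, j]
            back[t, j] = arg
        delta = new
    path = np.zeros(T, dtype=np.int64)
    best = delta[0]
    arg = 0
    for i in range(1, K):
        if delta[i] > best:
            best = delta[i]
            arg = i
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, best


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _fb_core = njit(cache=True)(_fb_core)
    _viterbi_core = njit(cache=True)(_viterbi_core)
except ImportError:  # pragma: no cover
    logger.info("numba unavailable; using pure-NumPy chain recursions")


def forward_backward(log_emissions: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward.  Returns (gamma, log-likelihood)."""
    log_b = np.asarray(log_emissions, dtype=float)
    if log_b.ndim != 2 or log_b.shape[1] != len(pi) or A.shape != (len(pi), len(pi)):
        raise ValueError("inconsistent dimensions")
    offsets = log_b.max(axis=1)
    if not np.all(np.isfinite(offsets)):
        raise ValueError("a bin has zero emission probability in every state")
    b = np.exp(log_b - offsets[:, None])
    gamma, log_c = _fb_core(
        np.ascontiguousarray(b), np.ascontiguousarray(A, dtype=float),
        np.ascontiguousarray(pi, dtype=float),
    )
    return gamma, float(log_c + offsets.sum())


def expected_transitions(log_emissions: np.ndarray, A: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Expected transition counts sum_t xi_t (for the optional A update)."""
    log_b = np.asarray(log_emissions, dtype=float)
    offsets = log_b.max(axis=1)
    b = np.exp(log_b - offsets[:, None])
    T, K = b.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)
    a = pi * b[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = b[t] * (A.T @ alpha[t - 1])
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / c[t + 1]
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        xi = A * np.outer(alpha[t], b[t + 1] * beta[t + 1]) / c[t + 1]
        xi_sum += xi
    return xi_sum


def viterbi(log_emissions: np.ndarray, A: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Most probable state path (log-space; ties toward the lowest index)."""
    log_b = np.asarray(log_emissions, dtype=float)
    if log_b.ndim != 2 or log_b.shape[1] != len(pi) or A.shape != (len(pi), len(pi)):
        raise ValueError("inconsistent dimensions")
    with np.errstate(divide="ignore"):
        log_A = np.log(np.asarray(A, dtype=float))
        log_pi = np.log(np.asarray(pi, dtype=float))
    path, _ = _viterbi_core(
        np.ascontiguousarray(log_b), np.ascontiguousarray(log_A),
        np.ascontiguousarray(log_pi),
    )
    return path


# ---------------------------------------------------------------------------
# priors and EM

def _log_beta_pdf(x: float, a: float, b: float) -> float:
    if not (0 < x < 1):
        return -np.inf
    return (a - 1.0) * math.log(x) + (b - 1.0) * math.log1p(-x) - betaln(a, b)


def log_prior(params: ModelParams, hyper: HyperParams, states: Sequence[CopyState]) -> float:
    """Log prior density of the parameters (Dirichlet terms with delta = 1
    and the flat ploidy prior contribute only constants, computed exactly)."""
    lp = _log_beta_pdf(params.n, hyper.n_alpha, hyper.n_beta)
    if any(st.subclonal for st in states):
        lp += _log_beta_pdf(params.s, hyper.s_alpha, hyper.s_beta)
    if hyper.phi_rate > 0:
        lp += (
            hyper.phi_shape * math.log(hyper.phi_rate)
            + (hyper.phi_shape - 1.0) * math.log(params.phi)
            - hyper.phi_rate * params.phi
            - gammaln(hyper.phi_shape)
        )
    a, scale = hyper.lambda_shape, hyper.lambda_scale
    lp += float(
        np.sum(
            (a - 1.0) * np.log(params.lam)
            - params.lam / scale
            - gammaln(a)
            - a * math.log(scale)
        )
    )
    K = len(params.pi)
    d = hyper.pi_delta
    lp += float(gammaln(K * d) - K * gammaln(d) + (d - 1.0) * np.log(params.pi).sum())
    return float(lp)


def _weighted_q(
    n: float, s: float, phi: float,
    gamma: np.ndarray, l: np.ndarray, lam: np.ndarray,
    states: Sequence[CopyState], hyper: HyperParams,
) -> float:
    """Expected complete-data log posterior terms that depend on (n, s, phi)."""
    try:
        mu = state_means(n, s, phi, states)
    except ValueError:
        return -np.inf
    lp = student_t_logpdf(l[:, None], mu[None, :], lam[None, :], hyper.nu)
    val = float(np.sum(gamma * lp))
    val += _log_beta_pdf(n, hyper.n_alpha, hyper.n_beta)
    if any(st.subclonal for st in states):
        val += _log_beta_pdf(s, hyper.s_alpha, hyper.s_beta)
    if hyper.phi_rate > 0:
        val += (hyper.phi_shape - 1.0) * math.log(phi) - hyper.phi_rate * phi
    return val


def _maximize_coordinate(fun, current: float, bounds: tuple[float, float]) -> float:
    res = minimize_scalar(
        lambda x: -fun(x), bounds=bounds, method="bounded",
        options={"xatol": 2e-4, "maxiter": 60},
    )
    # keep the better of {candidate, current}: guarantees a monotone EM step
    if res.success and fun(float(res.x)) >= fun(current):
        return float(res.x)
    return current


def map_m_step(
    gamma: np.ndarray,
    l: np.ndarray,
    states: Sequence[CopyState],
    hyper: HyperParams,
    current: ModelParams,
    update_transitions: bool = False,
    xi_sum: np.ndarray | None = None,
) -> ModelParams:
    """MAP parameter updates given posterior state responsibilities.

    The precisions have a closed-form update through the Student's-t
    latent-scale weights u = (nu+1)/(nu + lambda (l-mu)^2); the global
    parameters (n, s, phi) are updated by bounded one-dimensional
    maximization of the penalized expected log posterior, one pass per
    call.  pi gets a Dirichlet MAP update; A is rebuilt from ``e`` unless
    ``update_transitions`` is set and expected transition counts are given.
    """
    l = np.asarray(l, dtype=float)
    nu = hyper.nu
    mu = state_means(current.n, current.s, current.phi, states)
    resid2 = (l[:, None] - mu[None, :]) ** 2
    u = (nu + 1.0) / (nu + current.lam[None, :] * resid2)
    g_sum = gamma.sum(axis=0)
    num = hyper.lambda_shape - 1.0 + 0.5 * g_sum
    den = 1.0 / hyper.lambda_scale + 0.5 * np.sum(gamma * u * resid2, axis=0)
    lam = np.maximum(num / den, 1e-8)

    has_subclonal = any(st.subclonal for st in states)
    n = _maximize_coordinate(
        lambda x: _weighted_q(x, current.s, current.phi, gamma, l, lam, states, hyper),
        current.n, N_BOUNDS,
    )
    phi = _maximize_coordinate(
        lambda x: _weighted_q(n, current.s, x, gamma, l, lam, states, hyper),
        current.phi, PHI_BOUNDS,
    )
    s = current.s
    if has_subclonal:
        s = _maximize_coordinate(
            lambda x: _weighted_q(n, x, phi, gamma, l, lam, states, hyper),
            current.s, S_BOUNDS,
        )

    pi = gamma[0] + hyper.pi_delta - 1.0
    pi = np.maximum(pi, 1e-12)
    pi = pi / pi.sum()

    if update_transitions and xi_sum is not None:
        A = xi_sum + hyper.A_delta - 1.0
        A = np.maximum(A, 1e-12)
        A = A / A.sum(axis=1, keepdims=True)
    else:
        A = current.A
    return ModelParams(n=n, s=s, phi=phi, lam=lam, A=A, pi=pi)


def _masks(l: LogRatioTrack, exclude_chr19: bool, include_chrX: bool):
    grid = l.grid
    base = l.valid.copy()
    if not include_chrX:
        base &= grid.autosome_mask
    chr19 = np.array(
        [str(c) in ("chr19", "19") for c in grid.chrom]
    )
    train = base & ~chr19 if exclude_chr19 else base.copy()
    return train, base


def run_em(
    l: LogRatioTrack,
    n0: float,
    phi0: float,
    hyper: HyperParams | None = None,
    states: Sequence[CopyState] | None = None,
    max_iter: int = 50,
    abs_tol: float = 1e-3,
    rel_tol: float = 1e-4,
    exclude_chr19: bool = True,
    include_chrX: bool = False,
    s0: float = 0.1,
    update_transitions: bool = False,
) -> EMResult:
    """Fit the HMM by EM from one (n0, phi0) initialization.

    Chromosome 19 is excluded from parameter estimation but retained for
    decoding (its handful of bins contributes little to learning yet the
    final solution should be genome-wide).  Convergence: the increase in
    the penalized objective F falls below max(abs_tol, rel_tol * |F|).
    """
    states = list(states) if states is not None else default_state_space()
    train_mask, decode_mask = _masks(l, exclude_chr19, include_chrX)
    if train_mask.sum() < 100:
        raise ValueError(f"only {int(train_mask.sum())} bins available for EM (need >= 100)")
    data = l.l[train_mask]
    if hyper is None:
        hyper = default_hyperparams(data, states)
    K = len(states)
    A = transition_matrix(K, hyper.e)
    var = float(np.var(data))
    params = ModelParams(
        n=float(np.clip(n0, *N_BOUNDS)), s=s0, phi=float(np.clip(phi0, *PHI_BOUNDS)),
        lam=np.full(K, 1.0 / max(var, 1e-6)), A=A, pi=np.full(K, 1.0 / K),
    )

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = state_means(params.n, params.s, params.phi, states)
        log_b = student_t_logpdf(data[:, None], mu[None, :], params.lam[None, :], hyper.nu)
        gamma, ll = forward_backward(log_b, params.A, params.pi)
        F = ll + log_prior(params, hyper, states)
        if not np.isfinite(F):
            raise ValueError("non-finite EM objective")
        trace.append(F)
        if len(trace) > 1:
            delta = trace[-1] - trace[-2]
            if delta < max(abs_tol, rel_tol * abs(trace[-2])):
                converged = True
                break
        xi_sum = (
            expected_transitions(log_b, params.A, params.pi) if update_transitions else None
        )
        params = map_m_step(
            gamma, data, states, hyper, params,
            update_transitions=update_transitions, xi_sum=xi_sum,
        )

    # decode-set posteriors under the converged parameters
    mu = state_means(params.n, params.s, params.phi, states)
    decode_data = l.l[decode_mask]
    log_b_dec = student_t_logpdf(
        decode_data[:, None], mu[None, :], params.lam[None, :], hyper.nu
    )
    gamma_dec, _ = forward_backward(log_b_dec, params.A, params.pi)
    return EMResult(
        params=params, F=trace[-1], gamma=gamma_dec, loglik_trace=trace,
        iterations=it, init=(float(n0), float(phi0)), states=states, hyper=hyper,
        train_mask=train_mask, decode_mask=decode_mask, converged=converged,
    )


def decode_path(em: EMResult, l: LogRatioTrack) -> np.ndarray:
    """Viterbi path over the decode bins under the converged parameters."""
    mu = state_means(em.params.n, em.params.s, em.params.phi, em.states)
    data = l.l[em.decode_mask]
    log_b = student_t_logpdf(data[:, None], mu[None, :], em.params.lam[None, :], em.hyper.nu)
    return viterbi(log_b, em.params.A, em.params.pi)


def run_restarts(
    l: LogRatioTrack,
    hyper: HyperParams | None = None,
    states: Sequence[CopyState] | None = None,
    n0_grid: Sequence[float] = DEFAULT_N0_GRID,
    phi0_grid: Sequence[float] = DEFAULT_PHI0_GRID,
    **em_kwargs,
) -> list[EMResult]:
    """EM over the full initialization grid; individual failures are logged
    and skipped, but at least one restart must succeed."""
    if hyper is None:
        hyper = default_hyperparams(l, list(states) if states else default_state_space())
    results: list[EMResult] = []
    for phi0 in phi0_grid:
        for n0 in n0_grid:
            try:
                results.append(run_em(l, n0, phi0, hyper=hyper, states=states, **em_kwargs))
            except Exception as exc:  # noqa: BLE001 - isolate per-restart failures
                logger.warning("EM restart (n0=%.2f, phi0=%.1f) failed: %s", n0, phi0, exc)
    if not results:
        raise RuntimeError("all EM restarts failed")
    return results
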