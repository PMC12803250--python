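"""Admixture-aware time-series inference of selection coefficients.

The model: K ancestry components evolve as independent Wright-Fisher
populations of constant (haploid) size 2N.  With time t counted in
generations before present, the allele count F_{t-1,k} given f_{t,k} and
the selection coefficient s_{t,k} is Binomial(2N, f'(f_{t,k}, s_{t,k})),
where f' = f(1+s)/(1+fs) is the post-mating frequency.  Each dated haploid
sample i at time t carries ancestry loadings q_ti (from ADMIXTURE); its
latent ancestry z_ti ~ Categorical(q_ti) and its allele
a_ti | z_ti = k ~ Bernoulli(f_{t,k}).

Inference is a Gibbs sampler cycling

    f | a, Z, s   -- particle filter over {0..2N}^K with backward tracing
    Z | a, f, Q   -- independent categorical draws
    s | f         -- per-coordinate MALA against the binomial transition
                     likelihood plus Gaussian smoothing priors
    (alpha, beta) | s  -- conjugate Gamma updates (fully-Bayesian mode)

The smoothing prior penalizes changes of s over time (precision alpha) and
differences between ancestries at the same time (precision beta):
log prior = -alpha/2 sum_{t,k} (s_tk - s_{t-1,k})^2
            -beta/2 sum_t sum_{i != j} (s_ti - s_tj)^2.
Defaults alpha = 2.0 and beta = alpha/100; in fully-Bayesian mode both get
Gamma hyperpriors and the standard conjugate updates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .popdata import DatedSample, ValidationError
from .scan import NumericalError
from .wfsim import selection_update

logger = logging.getLogger(__name__)

__all__ = [
    "ParticleSet",
    "SelectionSurface",
    "SmoothingHyperparams",
    "PosteriorDraws",
    "GibbsConfig",
    "FilterHistory",
    "post_mating_frequency",
    "transition_particles",
    "update_weights",
    "resample_if_needed",
    "run_filter",
    "sample_trajectory",
    "sample_latent",
    "sample_selection",
    "sample_hyperparams",
    "run_gibbs",
]

_TARGET_ACCEPT = 0.57


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ParticleSet:
    """Weighted atoms on {0..2N}^K approximating one time-slice posterior."""

    atoms: np.ndarray  # (P, K) integer allele counts
    weights: np.ndarray  # (P,) nonnegative, sum 1

    def __post_init__(self):
        atoms = np.asarray(self.atoms)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "atoms", atoms)
        object.__setattr__(self, "weights", w)
        if atoms.ndim != 2 or atoms.shape[0] < 2:
            raise ValidationError("need a (P, K) atom array with P >= 2")
        if w.shape != (atoms.shape[0],):
            raise ValidationError("weights shape mismatch")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("weights must be nonnegative and sum to 1")

    @property
    def ess(self) -> float:
        return float(1.0 / np.sum(self.weights**2))


@dataclass(frozen=True)
class SelectionSurface:
    """s_{t,k} for t = 1..T generations before present, K ancestries."""

    s: np.ndarray  # (T, K); row t-1 governs the transition t -> t-1
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        s = np.atleast_2d(np.asarray(self.s, dtype=float))
        object.__setattr__(self, "s", s)
        if not np.all(np.isfinite(s)):
            raise ValidationError("selection surface must be finite")
        if self.times is None:
            object.__setattr__(self, "times", np.arange(1, s.shape[0] + 1))


@dataclass(frozen=True)
class SmoothingHyperparams:
    """Smoothing precisions and their Gamma hyperprior parameters."""

    alpha: float = 2.0
    beta: float = 2.0 / 100.0
    a_alpha: float = 1.0
    b_alpha: float = 1.0
    a_beta: float = 1.0
    b_beta: float = 1.0

    def __post_init__(self):
        for name in ("alpha", "beta", "a_alpha", "b_alpha", "a_beta", "b_beta"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class PosteriorDraws:
    s: np.ndarray  # (D, T, K)
    f: np.ndarray  # (D, T+1, K)
    alpha: np.ndarray  # (D,)
    beta: np.ndarray  # (D,)
    accept_rate: float
    seed: Optional[int]


@dataclass(frozen=True)
class GibbsConfig:
    N: int = 10_000  # effective size; 2N is the binomial denominator
    particles: int = 1000
    iterations: int = 2000
    burn_in: int = 500
    thin: int = 5
    mode: str = "fixed"  # "fixed" | "bayes"
    hyper: SmoothingHyperparams = field(default_factory=SmoothingHyperparams)
    resample_threshold: float = 0.5
    mala_step: float = 0.05
    s_sweeps: int = 10  # MALA sweeps per Gibbs iteration (filter cost dominates)
    seed: Optional[int] = None

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ValidationError("iterations must exceed burn_in")
        if self.mode not in ("fixed", "bayes"):
            raise ValidationError("mode must be 'fixed' or 'bayes'")


@dataclass
class FilterHistory:
    """Everything a backward trajectory draw needs from one filter pass."""

    atoms: list  # atoms[t] is (P, K) at time t, t = 0..T
    weights: list  # weights[t] is (P,)
    parents: list  # parents[t] maps level-t particles into level t+1, t = 0..T-1
    ess: list
    loglik: float
    two_n: int


@dataclass(frozen=True)
class _SampleArrays:
    """Dated samples binned to integer generations."""

    T: int
    K: int
    a_by_t: dict  # t -> (n_t,) int array
    q_by_t: dict  # t -> (n_t, K)
    idx_by_t: dict  # t -> (n_t,) global sample index
    n_total: int


def _bin_samples(samples: Sequence[DatedSample], T: Optional[int] = None) -> _SampleArrays:
    if not samples:
        raise ValidationError("no dated samples supplied")
    K = len(samples[0].loadings)
    times = sorted({s.time for s in samples})
    if len(times) < 2:
        raise ValidationError("samples must span at least 2 distinct times")
    T_eff = T if T is not None else max(times)
    T_eff = max(T_eff, 1)
    a_by_t: dict = {}
    q_by_t: dict = {}
    idx_by_t: dict = {}
    for i, s in enumerate(samples):
        a_by_t.setdefault(s.time, []).append(s.allele)
        q_by_t.setdefault(s.time, []).append(s.loadings)
        idx_by_t.setdefault(s.time, []).append(i)
    return _SampleArrays(
        T=T_eff,
        K=K,
        a_by_t={t: np.array(v, dtype=np.int64) for t, v in a_by_t.items()},
        q_by_t={t: np.array(v, dtype=float) for t, v in q_by_t.items()},
        idx_by_t={t: np.array(v, dtype=np.int64) for t, v in idx_by_t.items()},
        n_total=len(samples),
    )


# ---------------------------------------------------------------------------
# particle-filter primitives


def post_mating_frequency(f, s):
    """Allele frequency immediately after mating: f(1+s)/(1+fs)."""
    return selection_update(f, s)


def transition_particles(
    particles: ParticleSet,
    s_t: np.ndarray,
    N: int,
    rng: Optional[np.random.Generator] = None,
) -> ParticleSet:
    """One generation of drift+selection applied to every atom.

    Each ancestry's count is redrawn Binomial(2N, f'(count/2N, s_tk));
    weights are untouched (the transition is a prior move).
    """
    rng = rng or np.random.default_rng()
    two_n = 2 * N
    f = particles.atoms / two_n
    s_t = np.broadcast_to(np.asarray(s_t, dtype=float), (f.shape[1],))
    p = np.empty_like(f)
    for k in range(f.shape[1]):
        p[:, k] = selection_update(f[:, k], s_t[k])
    return ParticleSet(atoms=rng.binomial(two_n, p), weights=particles.weights)


def _log_emission(
    atoms: np.ndarray,
    two_n: int,
    a: np.ndarray,
    q: np.ndarray,
    z: Optional[np.ndarray],
) -> np.ndarray:
    """Per-particle log-likelihood of the samples observed at one time.

    With latent ancestries ``z`` given, the emission per sample is
    f_z^a (1-f_z)^(1-a); without, it is marginalized over the loadings:
    sum_k q_k f_k^a (1-f_k)^(1-a).
    """
    f = atoms / two_n  # (P, K)
    with np.errstate(divide="ignore"):
        if z is not None:
            fz = f[:, z]  # (P, n)
            e = np.where(a[None, :] == 1, fz, 1.0 - fz)
            return np.sum(np.log(e), axis=1)
        emis = np.where(a[None, None, :] == 1, f[:, :, None], 1.0 - f[:, :, None])
        mix = np.einsum("nk,pkn->pn", q, emis)  # (P, n)
        return np.sum(np.log(mix), axis=1)


def update_weights(
    particles: ParticleSet,
    a: np.ndarray,
    q: np.ndarray,
    N: int,
    z: Optional[np.ndarray] = None,
    time_label: Optional[int] = None,
):
    """Multiply weights by the data likelihood at one time and renormalize.

    Returns ``(ParticleSet, log_normalizer)``; the normalizer accumulates
    into the filter's marginal-likelihood estimate.  Raises
    :class:`NumericalError` if the data are impossible under every atom.
    """
    a = np.asarray(a, dtype=np.int64)
    if a.size == 0:
        return particles, 0.0
    with np.errstate(divide="ignore"):
        logw = np.where(particles.weights > 0, np.log(particles.weights), -np.inf)
    logw = logw + _log_emission(particles.atoms, 2 * N, a, np.asarray(q, dtype=float), z)
    m = np.max(logw)
    if not np.isfinite(m):
        raise NumericalError(
            f"all particle weights vanished at time {time_label}: data impossible "
            "under every atom"
        )
    w = np.exp(logw - m)
    tot = w.sum()
    return ParticleSet(atoms=particles.atoms, weights=w / tot), float(m + np.log(tot))


def resample_if_needed(
    particles: ParticleSet,
    threshold_fraction: float,
    rng: Optional[np.random.Generator] = None,
):
    """Systematic resampling when ESS drops below threshold_fraction * P.

    Returns ``(ParticleSet, parent_indices)``; parents are the identity when
    no resampling was triggered, preserving backward-trace bookkeeping.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    P = particles.atoms.shape[0]
    if particles.ess >= threshold_fraction * P:
        return particles, np.arange(P)
    rng = rng or np.random.default_rng()
    positions = (rng.random() + np.arange(P)) / P
    idx = np.searchsorted(np.cumsum(particles.weights), positions)
    idx = np.minimum(idx, P - 1)
    return (
        ParticleSet(atoms=particles.atoms[idx], weights=np.full(P, 1.0 / P)),
        idx,
    )


def run_filter(
    data: _SampleArrays,
    s: np.ndarray,
    N: int,
    P: int,
    rng: np.random.Generator,
    z: Optional[np.ndarray] = None,
    resample_threshold: float = 0.5,
) -> FilterHistory:
    """Particle filter sweep from the oldest time T to the present.

    Particles start uniform on {0..2N}^K at t = T (a flat prior on the
    oldest frequency), absorb the data at each time, and transition t ->
    t-1 under Binomial(2N, f'(f_t, s_t)).  Parent indices are stored at
    every step so trajectories can be traced backward.
    """
    T, K = data.T, data.K
    two_n = 2 * N
    s = np.atleast_2d(np.asarray(s, dtype=float))
    if s.shape != (T, K):
        raise ValidationError(f"selection surface must be ({T}, {K})")
    atoms = rng.integers(0, two_n + 1, size=(P, K))
    ps = ParticleSet(atoms=atoms, weights=np.full(P, 1.0 / P))
    loglik = 0.0

    def data_at(t):
        a = data.a_by_t.get(t)
        if a is None:
            return None
        zt = z[data.idx_by_t[t]] if z is not None else None
        return a, data.q_by_t[t], zt

    atoms_hist: list = [None] * (T + 1)
    weights_hist: list = [None] * (T + 1)
    parents: list = [None] * T
    ess_hist: list = [None] * (T + 1)

    d = data_at(T)
    if d is not None:
        ps, c = update_weights(ps, d[0], d[1], N, z=d[2], time_label=T)
        loglik += c
    atoms_hist[T] = ps.atoms
    weights_hist[T] = ps.weights
    ess_hist[T] = ps.ess

    for t in range(T - 1, -1, -1):
        ps, idx = resample_if_needed(ps, resample_threshold, rng)
        # transition t+1 -> t is governed by s at time t+1 (row index t)
        ps = transition_particles(ps, s[t], N, rng)
        d = data_at(t)
        if d is not None:
            ps, c = update_weights(ps, d[0], d[1], N, z=d[2], time_label=t)
            loglik += c
        atoms_hist[t] = ps.atoms
        weights_hist[t] = ps.weights
        parents[t] = idx
        ess_hist[t] = ps.ess
    return FilterHistory(
        atoms=atoms_hist,
        weights=weights_hist,
        parents=parents,
        ess=ess_hist,
        loglik=loglik,
        two_n=two_n,
    )


def sample_trajectory(history: FilterHistory, rng: np.random.Generator) -> np.ndarray:
    """Draw one frequency trajectory f_{0:T} by backward ancestry tracing.

    A terminal (t=0) particle is drawn by weight and its genealogy followed
    back to t=T.  Returns a (T+1, K) matrix of frequencies on the 1/(2N)
    grid.
    """
    if history.atoms[0] is None:
        raise ValueError("filter history is incomplete")
    T = len(history.parents)
    K = history.atoms[0].shape[1]
    path = np.empty((T + 1, K))
    j = rng.choice(len(history.weights[0]), p=history.weights[0])
    path[0] = history.atoms[0][j]
    for t in range(T):
        j = history.parents[t][j]
        path[t + 1] = history.atoms[t + 1][j]
    return path / history.two_n


def sample_latent(
    data: _SampleArrays, f: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw latent ancestry labels z_ti ~ P(z=k) propto q_tik f^a (1-f)^(1-a)."""
    z = np.zeros(data.n_total, dtype=np.int64)
    for t, a in data.a_by_t.items():
        q = data.q_by_t[t]
        ft = f[t]  # (K,)
        lik = np.where(a[:, None] == 1, ft[None, :], 1.0 - ft[None, :])
        p = q * lik
        tot = p.sum(axis=1, keepdims=True)
        if np.any(tot == 0):
            raise NumericalError(
                f"zero posterior mass for an ancestry label at time {t}"
            )
        p = p / tot
        u = rng.random(len(a))
        z[data.idx_by_t[t]] = (np.cumsum(p, axis=1) < u[:, None]).sum(axis=1)
    return z


# ---------------------------------------------------------------------------
# selection-coefficient sampling (MALA) and hyperparameter updates


def _s_loglik_terms(s_col: np.ndarray, f_from: np.ndarray, F_to: np.ndarray, two_n: int):
    """Unnormalized binomial log-likelihood and gradient for one ancestry.

    ``f_from[t-1]`` = f at time t, ``F_to[t-1]`` = allele count at time t-1;
    entries with f in {0, 1} carry no information about s and contribute 0.
    """
    informative = (f_from > 0) & (f_from < 1)
    denom = 1.0 + f_from * s_col
    p = np.where(informative, f_from * (1.0 + s_col) / denom, 0.5)
    ll = np.where(
        informative,
        F_to * np.log(p) + (two_n - F_to) * np.log1p(-p),
        0.0,
    )
    dp_ds = f_from * (1.0 - f_from) / denom**2
    grad = np.where(informative, (F_to - two_n * p) / (p * (1.0 - p)) * dp_ds, 0.0)
    return ll, grad


def _prior_terms(s: np.ndarray, t_idx: np.ndarray, k: int, alpha: float, beta: float):
    """Log prior and gradient for coordinates (t_idx, k) of the surface."""
    T, K = s.shape
    col = s[:, k]
    val = np.zeros(len(t_idx))
    grad = np.zeros(len(t_idx))
    has_prev = t_idx > 0
    has_next = t_idx < T - 1
    prev = col[np.maximum(t_idx - 1, 0)]
    nxt = col[np.minimum(t_idx + 1, T - 1)]
    cur = col[t_idx]
    val -= 0.5 * alpha * np.where(has_prev, (cur - prev) ** 2, 0.0)
    val -= 0.5 * alpha * np.where(has_next, (nxt - cur) ** 2, 0.0)
    grad -= alpha * np.where(has_prev, cur - prev, 0.0)
    grad += alpha * np.where(has_next, nxt - cur, 0.0)
    if K > 1:
        others = s[t_idx][:, [j for j in range(K) if j != k]]
        diffs = cur[:, None] - others
        val -= beta * np.sum(diffs**2, axis=1)
        grad -= 2.0 * beta * np.sum(diffs, axis=1)
    return val, grad


def sample_selection(
    s: np.ndarray,
    f: np.ndarray,
    N: int,
    alpha: float,
    beta: float,
    mala_step: float,
    rng: np.random.Generator,
):
    """One MALA sweep over every s_tk given a frequency trajectory.

    Coordinates are updated in a red-black (even/odd t) schedule per
    ancestry so that each block's conditional is evaluated against fixed
    neighbours.  The target combines the binomial transition likelihood of
    (f_{t-1} | f_t, s_t) with the Gaussian smoothing prior.  Returns
    ``(SelectionSurface, acceptance_rate)``.
    """
    s = np.atleast_2d(np.array(s, dtype=float, copy=True))
    f = np.atleast_2d(np.asarray(f, dtype=float))
    T, K = s.shape
    two_n = 2 * N
    eps = mala_step
    n_acc = 0
    n_tot = 0
    for k in range(K):
        F_to_all = np.rint(f[:-1, k] * two_n)  # counts at times 0..T-1
        f_from_all = f[1:, k]  # frequencies at times 1..T
        for parity in (0, 1):
            t_idx = np.arange(parity, T, 2)
            if len(t_idx) == 0:
                continue
            cur = s[t_idx, k]
            ll0, g_lik0 = _s_loglik_terms(cur, f_from_all[t_idx], F_to_all[t_idx], two_n)
            pr0, g_pr0 = _prior_terms(s, t_idx, k, alpha, beta)
            grad0 = g_lik0 + g_pr0
            noise = rng.standard_normal(len(t_idx))
            prop = cur + 0.5 * eps**2 * grad0 + eps * noise
            ok = prop > -0.999  # keep 1 + f s positive for all f in [0,1]
            prop_safe = np.where(ok, prop, cur)
            s_prop = s.copy()
            s_prop[t_idx, k] = prop_safe
            ll1, g_lik1 = _s_loglik_terms(
                prop_safe, f_from_all[t_idx], F_to_all[t_idx], two_n
            )
            pr1, g_pr1 = _prior_terms(s_prop, t_idx, k, alpha, beta)
            grad1 = g_lik1 + g_pr1
            if not np.all(np.isfinite(grad0)) or not np.all(np.isfinite(grad1)):
                raise NumericalError(
                    f"non-finite MALA gradient at ancestry {k}, times {t_idx}"
                )
            fwd = -((prop_safe - cur - 0.5 * eps**2 * grad0) ** 2) / (2 * eps**2)
            rev = -((cur - prop_safe - 0.5 * eps**2 * grad1) ** 2) / (2 * eps**2)
            log_ratio = (ll1 + pr1) - (ll0 + pr0) + rev - fwd
            accept = ok & (np.log(rng.random(len(t_idx))) < log_ratio)
            s[t_idx[accept], k] = prop_safe[accept]
            n_acc += int(accept.sum())
            n_tot += len(t_idx)
    return SelectionSurface(s=s), n_acc / max(n_tot, 1)


def sample_hyperparams(
    s: np.ndarray,
    hyper: SmoothingHyperparams,
    rng: np.random.Generator,
):
    """Conjugate Gamma draws of the smoothing precisions given the surface.

    alpha | s ~ Gamma(a_alpha + TK/2, b_alpha + (1/2) sum (s_tk - s_{t-1,k})^2)
    beta  | s ~ Gamma(a_beta + TK(K-1)/2, b_beta + (1/2) sum_{i!=j} (s_ti - s_tj)^2)

    (rate convention; with K = 1 the beta update reduces to its prior).
    """
    s = np.atleast_2d(np.asarray(s, dtype=float))
    T, K = s.shape
    ssum = float(np.sum(np.diff(s, axis=0) ** 2))
    shape_a = hyper.a_alpha + T * K / 2.0
    rate_a = hyper.b_alpha + 0.5 * ssum
    if K > 1:
        pair = 0.0
        for i in range(K):
            for j in range(K):
                if i != j:
                    pair += float(np.sum((s[:, i] - s[:, j]) ** 2))
    else:
        pair = 0.0
    shape_b = hyper.a_beta + T * K * (K - 1) / 2.0
    rate_b = hyper.b_beta + 0.5 * pair
    alpha = rng.gamma(shape_a, 1.0 / rate_a)
    beta = rng.gamma(shape_b, 1.0 / rate_b)
    return float(alpha), float(beta)


# ---------------------------------------------------------------------------
# Gibbs driver


def run_gibbs(
    samples: Sequence[DatedSample], config: GibbsConfig
):
    """Full posterior sampler for the selection surface.

    Returns ``(PosteriorDraws, summary)`` where summary is a long-format
    DataFrame with per-(t, k) posterior medians and 5-95% bands for both
    the selection coefficient and the allele frequency.
    """
    data = _bin_samples(samples)
    T, K = data.T, data.K
    rng = np.random.default_rng(config.seed)
    hyper = config.hyper
    alpha, beta = hyper.alpha, hyper.beta
    s = np.zeros((T, K))
    z: Optional[np.ndarray] = None
    step = config.mala_step
    kept_s, kept_f, kept_a, kept_b = [], [], [], []
    acc_sum, acc_n = 0.0, 0

    for it in range(config.iterations):
        hist = None
        for attempt in range(3):
            try:
                hist = run_filter(
                    data,
                    s,
                    config.N,
                    config.particles,
                    rng,
                    z=z,
                    resample_threshold=config.resample_threshold,
                )
                break
            except NumericalError:
                if attempt == 2:
                    raise
        f = sample_trajectory(hist, rng)
        z = sample_latent(data, f, rng) if K > 1 else np.zeros(data.n_total, dtype=np.int64)
        acc = 0.0
        for _ in range(config.s_sweeps):
            surf, acc_sweep = sample_selection(s, f, config.N, alpha, beta, step, rng)
            s = surf.s
            acc += acc_sweep / config.s_sweeps
        if config.mode == "bayes":
            alpha, beta = sample_hyperparams(s, hyper, rng)
        if it < config.burn_in:
            step = float(np.clip(step * np.exp(0.05 * (acc - _TARGET_ACCEPT)), 1e-5, 1.0))
        else:
            acc_sum += acc
            acc_n += 1
            if (it - config.burn_in) % config.thin == 0:
                kept_s.append(s.copy())
                kept_f.append(f.copy())
                kept_a.append(alpha)
                kept_b.append(beta)

    draws = PosteriorDraws(
        s=np.array(kept_s),
        f=np.array(kept_f),
        alpha=np.array(kept_a),
        beta=np.array(kept_b),
        accept_rate=acc_sum / max(acc_n, 1),
        seed=config.seed,
    )
    rows = []
    s_q = np.quantile(draws.s, [0.05, 0.5, 0.95], axis=0)
    f_q = np.quantile(draws.f, [0.05, 0.5, 0.95], axis=0)
    for t in range(T + 1):
        for k in range(K):
            rows.append(
                {
                    "t": t,
                    "k": k + 1,
                    "s_median": s_q[1, t - 1, k] if t >= 1 else np.nan,
                    "s_q05": s_q[0, t - 1, k] if t >= 1 else np.nan,
                    "s_q95": s_q[2, t - 1, k] if t >= 1 else np.nan,
                    "f_median": f_q[1, t, k],
                    "f_q05": f_q[0, t, k],
                    "f_q95": f_q[2, t, k],
                }
            )
    return draws, pd.DataFrame(rows)


def profile_smoothing(
    samples: Sequence[DatedSample],
    config: GibbsConfig,
    alphas: Sequence[float],
    beta_ratio: float = 0.01,
):
    """Average filter log-likelihood across a grid of smoothing strengths.

    A light-weight aid for choosing alpha: for each candidate, a short
    fixed-hyperparameter Gibbs run is scored by the mean particle-filter
    marginal log-likelihood over its retained iterations.
    """
    rows = []
    for a in alphas:
        cfg = GibbsConfig(
            N=config.N,
            particles=config.particles,
            iterations=config.iterations,
            burn_in=config.burn_in,
            thin=config.thin,
            mode="fixed",
            hyper=SmoothingHyperparams(alpha=a, beta=max(a * beta_ratio, 1e-12)),
            resample_threshold=config.resample_threshold,
            mala_step=config.mala_step,
            seed=config.seed,
        )
        data = _bin_samples(samples)
        rng = np.random.default_rng(cfg.seed)
        s = np.zeros((data.T, data.K))
        lls = []
        for it in range(cfg.iterations):
            hist = run_filter(
                data, s, cfg.N, cfg.particles, rng, resample_threshold=cfg.resample_threshold
            )
            f = sample_trajectory(hist, rng)
            surf, _ = sample_selection(s, f, cfg.N, a, a * beta_ratio, cfg.mala_step, rng)
            s = surf.s
            if it >= cfg.burn_in:
                lls.append(hist.loglik)
        rows.append({"alpha": a, "beta": a * beta_ratio, "mean_loglik": float(np.mean(lls))})
    return pd.DataFrame(rows)
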