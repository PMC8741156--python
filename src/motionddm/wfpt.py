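"""Wiener first-passage-time core for the two-boundary diffusion model.

The decision process is a Wiener diffusion with drift ``v``, within-trial
noise ``s`` (fixed at 0.1 by convention to resolve the scaling degeneracy),
absorbing boundaries at 0 and ``a``, and starting point ``z = z_rel * a``.
Observed response time is first-passage time plus non-decision time ``ter``.

Densities use the dual small-time/large-time series representation with an
adaptive term count; defective CDFs use the exponential large-time series
integrated term by term, anchored to the closed-form absorption probability.
Both boundaries are mapped onto the "lower boundary" canonical form via the
reflection (v, w) -> (-v, 1 - w).

Units: time in seconds, evidence in the s = 0.1 convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "DiffusionParams",
    "fpt_density",
    "choice_and_cdf",
    "simulate_trial",
    "simulate_trials",
    "trial_loglik",
    "LOGLIK_PENALTY",
]

#: log-likelihood assigned to a responded trial with RT <= ter (instead of
#: -inf) so that DE-MCMC proposals into the invalid region are rejected
#: without producing NaNs in acceptance ratios.
LOGLIK_PENALTY = -1.0e10

_SERIES_ERR = 1e-10  # absolute tolerance of the standardized density series


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of a single diffusion process.

    a: boundary separation (> 0), z_rel: relative start point z/a in (0, 1),
    ter: non-decision time in seconds (>= 0), v: drift rate (signed; positive
    drives toward the upper bound), s: within-trial noise SD (default 0.1).
    """

    a: float
    z_rel: float = 0.5
    ter: float = 0.3
    v: float = 0.0
    s: float = 0.1

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if not (0.0 < self.z_rel < 1.0):
            raise ValueError(f"relative start point z_rel must be in (0,1), got {self.z_rel}")
        if self.ter < 0:
            raise ValueError(f"non-decision time ter must be >= 0, got {self.ter}")
        if not (self.s > 0):
            raise ValueError(f"noise SD s must be > 0, got {self.s}")


# ---------------------------------------------------------------------------
# numba kernels (unit-diffusion canonical form; caller rescales by 1/s)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _std_density(tt: float, w: float) -> float:
    """Standardized FPT density f(tt | v=0, a=1, w) at the lower bound.

    Chooses between the small-time and large-time series by comparing the
    number of terms each needs for absolute tolerance _SERIES_ERR.
    """
    err = _SERIES_ERR
    if tt <= 0.0:
        return 0.0
    # number of terms for the large-time series
    if math.pi * tt * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * err) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))
    # number of terms for the small-time series
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * err * math.sqrt(2.0 * math.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    p = 0.0
    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + ((K - 1) % 2)
        for k in range(lo, hi + 1):
            p += (w + 2.0 * k) * math.exp(-((w + 2.0 * k) ** 2) / (2.0 * tt))
        p *= 1.0 / math.sqrt(2.0 * math.pi * tt * tt * tt)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-(k * k) * (math.pi * math.pi) * tt / 2.0) * math.sin(
                k * math.pi * w
            )
        p *= math.pi
    if p < 0.0:
        p = 0.0
    return p


@njit(cache=True)
def _log_density_lower(t: float, v: float, a: float, w: float) -> float:
    """Log FPT density at the lower bound, unit diffusion, decision time t.
    Computed in log space so extreme drift/boundary proposals cannot
    overflow (returns -inf where the density vanishes)."""
    if t <= 0.0:
        return -np.inf
    tt = t / (a * a)
    p = _std_density(tt, w)
    if p <= 0.0:
        return -np.inf
    return math.log(p) - v * a * w - v * v * t / 2.0 - 2.0 * math.log(a)


@njit(cache=True)
def _density_lower(t: float, v: float, a: float, w: float) -> float:
    """FPT density at the lower bound, unit diffusion, decision time t."""
    lp = _log_density_lower(t, v, a, w)
    return math.exp(lp) if lp > -700.0 else 0.0


@njit(cache=True)
def _prob_lower(v: float, a: float, w: float) -> float:
    """Closed-form absorption probability at the lower bound, unit diffusion."""
    if v == 0.0:
        return 1.0 - w
    x = -2.0 * v * a
    if x > 500.0:  # strong negative drift: work in log space
        return 1.0 - math.exp(-2.0 * v * a * w - x)
    num = math.expm1(-2.0 * v * a * w)
    den = math.expm1(x)
    return 1.0 - num / den


@njit(cache=True)
def _cdf_lower(t: float, v: float, a: float, w: float) -> float:
    """Defective CDF of lower-bound passage at decision time t, unit diffusion.

    F(t) = P_lower - (pi / a^2) e^{-vaw} sum_k k sin(k pi w) e^{-lam_k t}/lam_k,
    lam_k = (v^2 + k^2 pi^2 / a^2) / 2.
    """
    if t <= 0.0:
        return 0.0
    plo = _prob_lower(v, a, w)
    # fold the exp(-vaw) prefactor into each term's exponent so strong
    # negative drift cannot overflow
    tail = 0.0
    k = 1
    while k < 100000:
        lam = (v * v + (k * math.pi / a) ** 2) / 2.0
        le = -v * a * w - lam * t
        mag = k * (math.exp(le) if le < 700.0 else math.exp(700.0)) / lam
        tail += mag * math.sin(k * math.pi * w)
        # terms are bounded by k e^{le}/lam; stop once negligible
        if mag < _SERIES_ERR and k > 2:
            break
        k += 1
    F = plo - math.pi / (a * a) * tail
    if F < 0.0:
        F = 0.0
    elif F > plo:
        F = plo
    return F


@njit(cache=True)
def _survivor(t: float, v: float, a: float, w: float) -> float:
    """P(no boundary reached by decision time t), unit diffusion."""
    if t <= 0.0:
        return 1.0
    s = 1.0 - _cdf_lower(t, v, a, w) - _cdf_lower(t, -v, a, 1.0 - w)
    if s < 0.0:
        s = 0.0
    return s


@njit(cache=True)
def _simulate_batch(
    v: np.ndarray,
    a: float,
    z_rel: float,
    ter: float,
    s: float,
    deadline: float,
    dt: float,
    seed: int,
):
    """Euler-Maruyama simulation with Brownian-bridge crossing correction.

    Returns (rt, outcome): outcome 1 = upper bound, 0 = lower, -1 = timeout
    (first passage after the deadline). rt is total RT (ter included); for
    timeouts rt is NaN.
    """
    np.random.seed(seed)
    n = v.shape[0]
    rt = np.empty(n)
    outcome = np.empty(n, dtype=np.int8)
    horizon = deadline - ter
    sqdt = math.sqrt(dt)
    for i in range(n):
        x = z_rel * a
        t = 0.0
        out = np.int8(-1)
        hit_t = np.nan
        while t < horizon:
            xn = x + v[i] * dt + s * sqdt * np.random.normal()
            if xn >= a:
                out = np.int8(1)
                hit_t = t + 0.5 * dt
                break
            if xn <= 0.0:
                out = np.int8(0)
                hit_t = t + 0.5 * dt
                break
            # probability the bridge crossed a bound within the step
            pu = math.exp(-2.0 * (a - x) * (a - xn) / (s * s * dt))
            pl = math.exp(-2.0 * x * xn / (s * s * dt))
            u = np.random.random()
            if u < pu:
                out = np.int8(1)
                hit_t = t + 0.5 * dt
                break
            if u < pu + pl:
                out = np.int8(0)
                hit_t = t + 0.5 * dt
                break
            x = xn
            t += dt
        if out >= 0 and ter + hit_t <= deadline:
            rt[i] = ter + hit_t
            outcome[i] = out
        else:
            rt[i] = np.nan
            outcome[i] = np.int8(-1)
    return rt, outcome


@njit(cache=True)
def _loglik_trials(
    rt: np.ndarray,
    resp_upper: np.ndarray,
    timeout: np.ndarray,
    sign: np.ndarray,
    easy: np.ndarray,
    a: float,
    z_rel: float,
    ter: float,
    v_easy: float,
    v_hard: float,
    s: float,
    deadline: float,
    penalty: float,
) -> float:
    """Summed log-likelihood of one participant's trials (unit-rescaled inside).

    sign is the stimulus-coded drift multiplier (+1 rightward, -1 leftward);
    resp_upper marks responses at the upper (rightward) bound. Timeout trials
    contribute the log survivor function at the decision-time deadline.
    """
    if not (a > 0.0) or not (0.0 < z_rel < 1.0) or ter < 0.0:
        return -np.inf
    au = a / s
    ll = 0.0
    # lazily computed log-survivor for the 4 (sign, difficulty) combinations
    surv = np.full(4, np.nan)
    horizon = deadline - ter
    for i in range(rt.shape[0]):
        vi = v_easy if easy[i] else v_hard
        vu = sign[i] * vi / s
        if timeout[i]:
            idx = (0 if sign[i] > 0 else 2) + (0 if easy[i] else 1)
            if math.isnan(surv[idx]):
                sv = _survivor(horizon, vu, au, z_rel)
                surv[idx] = math.log(sv) if sv > 0.0 else penalty
            ll += surv[idx]
        else:
            td = rt[i] - ter
            if td <= 0.0:
                ll += penalty
                continue
            if resp_upper[i]:
                ld = _log_density_lower(td, -vu, au, 1.0 - z_rel)
            else:
                ld = _log_density_lower(td, vu, au, z_rel)
            ll += ld if np.isfinite(ld) else penalty
    return ll


@njit(cache=True)
def _loglik_subjects_batch(
    params: np.ndarray,  # (P, 5): a, z_rel, ter, v_diff, v_mean
    offsets: np.ndarray,  # (P+1,) trial offsets into the flat arrays
    rt: np.ndarray,
    resp_upper: np.ndarray,
    timeout: np.ndarray,
    sign: np.ndarray,
    easy: np.ndarray,
    s: float,
    deadline: float,
    penalty: float,
) -> np.ndarray:
    P = params.shape[0]
    out = np.empty(P)
    for p in range(P):
        lo, hi = offsets[p], offsets[p + 1]
        v_easy = params[p, 4] + params[p, 3] / 2.0
        v_hard = params[p, 4] - params[p, 3] / 2.0
        out[p] = _loglik_trials(
            rt[lo:hi],
            resp_upper[lo:hi],
            timeout[lo:hi],
            sign[lo:hi],
            easy[lo:hi],
            params[p, 0],
            params[p, 1],
            params[p, 2],
            v_easy,
            v_hard,
            s,
            deadline,
            penalty,
        )
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _unit(params: DiffusionParams) -> tuple[float, float, float]:
    """Rescale to the unit-diffusion canonical form (a/s, v/s, w)."""
    return params.a / params.s, params.v / params.s, params.z_rel


def fpt_density(t, bound: str, params: DiffusionParams):
    """Defective first-passage density (1/s) of hitting `bound` at total time t.

    t is total response time (non-decision time included); density is 0 for
    t <= ter. Vectorized over t.
    """
    _check_bound(bound)
    au, vu, w = _unit(params)
    if bound == "upper":
        vu, w = -vu, 1.0 - w
    tarr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.array([_density_lower(ti - params.ter, vu, au, w) for ti in tarr])
    return out if np.ndim(t) else float(out[0])


def choice_and_cdf(t, bound: str, params: DiffusionParams):
    """Return (P(bound), defective CDF_bound(t), survivor S(t)) at total time t.

    P(bound) is the closed-form absorption probability; the defective CDF
    asymptotes to it; S(t) = 1 - CDF_upper(t) - CDF_lower(t), with S(t)=1 for
    t <= ter.
    """
    _check_bound(bound)
    au, vu, w = _unit(params)
    if bound == "upper":
        pb = 1.0 - _prob_lower(vu, au, w)
    else:
        pb = _prob_lower(vu, au, w)
    tarr = np.atleast_1d(np.asarray(t, dtype=float))
    cdf = np.empty_like(tarr)
    surv = np.empty_like(tarr)
    for i, ti in enumerate(tarr):
        td = ti - params.ter
        if bound == "upper":
            cdf[i] = _cdf_lower(td, -vu, au, 1.0 - w)
        else:
            cdf[i] = _cdf_lower(td, vu, au, w)
        surv[i] = _survivor(td, vu, au, w)
    if np.ndim(t):
        return pb, cdf, surv
    return pb, float(cdf[0]), float(surv[0])


def simulate_trials(
    n: int,
    params: DiffusionParams,
    deadline: float,
    rng: np.random.Generator,
    dt: float = 5e-4,
    v: np.ndarray | None = None,
):
    """Simulate n first-passage trials; returns (rt, outcome).

    outcome: 1 upper bound, 0 lower bound, -1 timeout (rt NaN). `v` may give
    a per-trial signed drift (stimulus coding); defaults to params.v.
    """
    if deadline <= params.ter:
        raise ValueError("deadline must exceed the non-decision time")
    varr = np.full(n, params.v) if v is None else np.asarray(v, dtype=float)
    seed = int(rng.integers(0, 2**31 - 1))
    return _simulate_batch(
        varr, params.a, params.z_rel, params.ter, params.s, deadline, dt, seed
    )


def simulate_trial(params: DiffusionParams, deadline: float, rng: np.random.Generator, dt: float = 5e-4):
    """Simulate one trial; returns (outcome, rt) with outcome in {'upper','lower','timeout'}."""
    rt, out = simulate_trials(1, params, deadline, rng, dt=dt)
    label = {1: "upper", 0: "lower", -1: "timeout"}[int(out[0])]
    return label, float(rt[0])


def trial_loglik(
    rt: float | None,
    response: str | None,
    timeout: bool,
    params: DiffusionParams,
    deadline: float = 2.5,
    penalty: float = LOGLIK_PENALTY,
) -> float:
    """Log-likelihood contribution of a single trial.

    Responded trials contribute log density at the observed RT on the response
    bound; timeouts contribute log S(deadline). Responded trials with
    t <= ter get the configured penalty (finite, for sampler stability).
    """
    au, vu, w = _unit(params)
    if timeout:
        sv = _survivor(deadline - params.ter, vu, au, w)
        return math.log(sv) if sv > 0 else penalty
    if rt is None or response not in ("upper", "lower"):
        raise ValueError("responded trial needs rt and response in {'upper','lower'}")
    if rt <= 0:
        raise ValueError("responded trial must have rt > 0")
    d = fpt_density(rt, response, params)
    return math.log(d) if d > 0 else penalty


def _check_bound(bound: str) -> None:
    if bound not in ("upper", "lower"):
        raise ValueError(f"bound must be 'upper' or 'lower', got {bound!r}")
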