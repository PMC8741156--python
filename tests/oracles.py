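"""Independent numerical oracles used by the tests.

Kept deliberately naive and separate from the package's computational paths:
a plain Euler-Maruyama first-passage simulator (no bridge correction) and a
scipy-based scalar log-density summer.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def euler_fpt(
    n: int,
    v: float,
    a: float,
    z_rel: float,
    ter: float,
    s: float,
    rng: np.random.Generator,
    dt: float = 1e-4,
    horizon: float = 10.0,
):
    """Brute-force Euler simulation of the Wiener first-passage process.

    Returns (rt, upper) for trials absorbed before `horizon` (decision time);
    unabsorbed trials are dropped. rt includes ter.
    """
    x = np.full(n, z_rel * a)
    alive = np.arange(n)
    rt = np.full(n, np.nan)
    upper = np.zeros(n, dtype=bool)
    sq = s * np.sqrt(dt)
    t = 0.0
    while len(alive) and t < horizon:
        x = x + v * dt + sq * rng.standard_normal(len(alive))
        t += dt
        hit_up = x >= a
        hit_lo = x <= 0.0
        done = hit_up | hit_lo
        if done.any():
            idx = alive[done]
            rt[idx] = ter + t
            upper[idx] = hit_up[done]
            alive = alive[~done]
            x = x[~done]
    ok = ~np.isnan(rt)
    return rt[ok], upper[ok]


def scalar_subject_logdensity(params, hypers, group) -> float:
    """scipy-based sum of the five group-level scalar log densities."""
    c = 1.0 if group == "dyslexia" else -1.0
    out = 0.0
    for name, x, lo, hi in (
        ("a", params.a, 0.0, np.inf),
        ("z", params.z_rel, 0.0, 1.0),
        ("ter", params.ter, 0.0, np.inf),
        ("v.diff", params.v_diff, -np.inf, np.inf),
        ("v.mean", params.v_mean, -np.inf, np.inf),
    ):
        loc = hypers.mu[name] + c * hypers.delta[name]
        sc = hypers.sigma[name]
        if np.isinf(lo) and np.isinf(hi):
            out += stats.norm.logpdf(x, loc, sc)
        else:
            out += stats.truncnorm.logpdf(x, (lo - loc) / sc, (hi - loc) / sc, loc, sc)
    return float(out)
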