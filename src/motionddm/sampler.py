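"""Blocked differential-evolution MCMC (DE-MCMC).

Each proposal for a parameter block is current + gamma*(chain_r1 - chain_r2)
+ jitter, with gamma = 2.38/sqrt(2d) for a d-dimensional block (occasionally
gamma = 1 for mode jumping), Metropolis-accepted. Chains are updated one at
a time against the current ensemble, which preserves detailed balance on the
extended chain product. A migration step periodically proposes cyclic state
copies among a random subset of chains, each Metropolis-accepted, to rescue
outlier chains early in the run.

Hierarchy-aware fitting: models expose conditionally independent subject
blocks plus group-level blocks (see `HierarchicalDDM`); within one chain all
subject blocks are proposed and accepted simultaneously (their posterior
factors are disjoint given the hypers), which keeps the expensive trial
likelihood evaluations batched. Subject likelihoods and group-prior terms
are cached so group-level updates never re-touch the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "crossover_step",
    "migration_step",
    "run",
    "gelman_rubin",
]


@dataclass(frozen=True)
class SamplerConfig:
    n_chains: int = 15
    n_iter: int = 4000
    burn_in: int = 1500
    migration_interval: int | None = 14
    migration_window: tuple[int, int] | None = (500, 1100)
    gamma_scale: float | None = None  # None -> 2.38/sqrt(2d) per block
    mode_jump_prob: float = 0.1
    jitter: float = 0.001
    init: str = "prior"  # 'prior' | 'data'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.n_chains < 3:
            raise ValueError("DE-MCMC needs at least 3 chains")
        if self.migration_window is not None:
            lo, hi = self.migration_window
            if not (0 <= lo <= hi <= self.n_iter):
                raise ValueError("migration window must lie within [0, n_iter]")


@dataclass
class PosteriorSamples:
    """chain x iteration x parameter array with burn-in metadata."""

    samples: np.ndarray
    param_names: list
    burn_in: int
    acceptance: dict = field(default_factory=dict)
    config: SamplerConfig | None = None

    def post_burn(self) -> np.ndarray:
        return self.samples[:, self.burn_in :, :]

    def flat(self) -> np.ndarray:
        pb = self.post_burn()
        return pb.reshape(-1, pb.shape[-1])

    def get(self, name: str) -> np.ndarray:
        return self.flat()[:, self.param_names.index(name)]

    def post_burn_mean(self) -> dict:
        m = self.flat().mean(axis=0)
        return dict(zip(self.param_names, m))

    def rhat(self) -> dict:
        return gelman_rubin(self)

    def summary(self):
        import pandas as pd

        fl = self.flat()
        rh = self.rhat()
        return pd.DataFrame(
            {
                "mean": fl.mean(0),
                "sd": fl.std(0, ddof=1),
                "q2.5": np.percentile(fl, 2.5, axis=0),
                "median": np.percentile(fl, 50, axis=0),
                "q97.5": np.percentile(fl, 97.5, axis=0),
                "rhat": [rh[n] for n in self.param_names],
            },
            index=self.param_names,
        )

    def save(self, path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), samples=self.samples)
        meta = {
            "param_names": list(self.param_names),
            "burn_in": int(self.burn_in),
            "acceptance": {k: float(v) for k, v in self.acceptance.items()},
            "config": asdict(self.config) if self.config else None,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        path = Path(path)
        samples = np.load(path.with_suffix(".npz"))["samples"]
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = meta["config"]
        if cfg is not None:
            cfg["migration_window"] = tuple(cfg["migration_window"]) if cfg["migration_window"] else None
            cfg = SamplerConfig(**cfg)
        return cls(samples, meta["param_names"], meta["burn_in"], meta["acceptance"], cfg)


# ---------------------------------------------------------------------------
# generic single-target operations
# ---------------------------------------------------------------------------


def _de_proposal(states, c, idx, rng, gamma_scale, mode_jump_prob, jitter):
    n_chains = states.shape[0]
    r1, r2 = _pick_pair(n_chains, c, rng)
    d = len(idx)
    gamma = gamma_scale if gamma_scale is not None else 2.38 / np.sqrt(2.0 * d)
    if mode_jump_prob > 0 and rng.random() < mode_jump_prob:
        gamma = 1.0
    eps = rng.uniform(-jitter, jitter, d)
    return states[c, idx] + gamma * (states[r1, idx] - states[r2, idx]) + eps


def _pick_pair(n_chains, c, rng):
    r1 = int(rng.integers(n_chains - 1))
    r1 += r1 >= c
    r2 = int(rng.integers(n_chains - 2))
    for taken in sorted((c, r1)):
        r2 += r2 >= taken
    return r1, r2


def crossover_step(
    states: np.ndarray,
    logp,
    block: np.ndarray | None,
    rng: np.random.Generator,
    logp_cur: np.ndarray | None = None,
    gamma_scale: float | None = None,
    mode_jump_prob: float = 0.1,
    jitter: float = 0.001,
):
    """One DE crossover sweep over all chains on the given block (indices
    into the state vector; None = all). `logp` maps a full state vector to a
    log density. Returns (states, logp_cur, n_accepted); states are updated
    in place, chains sequentially against the current ensemble."""
    n_chains, dim = states.shape
    if n_chains < 3:
        raise ValueError("crossover needs at least 3 chains")
    idx = np.arange(dim) if block is None else np.asarray(block)
    if logp_cur is None:
        logp_cur = np.array([logp(states[c]) for c in range(n_chains)])
    acc = 0
    for c in range(n_chains):
        prop = states[c].copy()
        prop[idx] = _de_proposal(states, c, idx, rng, gamma_scale, mode_jump_prob, jitter)
        lp = logp(prop)
        if np.isnan(lp):
            raise _nan_error(prop)
        if np.log(rng.random()) < lp - logp_cur[c]:
            states[c] = prop
            logp_cur[c] = lp
            acc += 1
    return states, logp_cur, acc


def migration_step(states: np.ndarray, logp, rng: np.random.Generator, logp_cur=None):
    """Cyclic migration: a random subset of chains each proposes to adopt the
    previous subset member's state, Metropolis-accepted. Returns
    (states, logp_cur, n_accepted)."""
    n_chains = states.shape[0]
    if logp_cur is None:
        logp_cur = np.array([logp(states[c]) for c in range(n_chains)])
    k = int(rng.integers(1, n_chains + 1))
    members = rng.choice(n_chains, size=k, replace=False)
    donor_states = states[members].copy()
    donor_lp = logp_cur[members].copy()
    acc = 0
    for m in range(k):
        recv = members[m]
        dlp = donor_lp[m - 1]  # cyclic: member m receives from member m-1
        if np.log(rng.random()) < dlp - logp_cur[recv]:
            states[recv] = donor_states[m - 1]
            logp_cur[recv] = dlp
            acc += 1
    return states, logp_cur, acc


# ---------------------------------------------------------------------------
# the blocked hierarchical runner
# ---------------------------------------------------------------------------


def _nan_error(state):
    err = RuntimeError(
        "log-posterior returned NaN; offending state attached as err.state "
        f"(first entries: {np.asarray(state).ravel()[:8]})"
    )
    err.state = np.asarray(state).copy()
    return err


def run(model, config: SamplerConfig | None = None, init=None) -> PosteriorSamples:
    """Sample the blocked hierarchical posterior of `model` with DE-MCMC.

    Per iteration and chain: all subject blocks are updated (conditionally
    independent, batched likelihood), then each group-level block in turn;
    migration is applied on its schedule. Returns all iterations; burn-in is
    recorded in the result and discarded by its summaries.
    """
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.seed)
    C, P, D = config.n_chains, model.P, getattr(model, "subject_dim", 0)
    G = D if P > 0 else 0
    H = len(model.hyper_blocks)
    nsub = P * D

    draw = init
    if draw is None:
        draw = model.data_informed_draw if config.init == "data" and hasattr(
            model, "data_informed_draw"
        ) else model.init_draw

    theta = np.empty((C, model.n_params))
    lik = np.zeros((C, P))
    sp = np.zeros((C, G, P))
    hp = np.zeros((C, H))
    for c in range(C):
        for attempt in range(100):
            theta[c] = draw(rng)
            if P > 0:
                lik[c] = model.loglik_subjects(theta[c, :nsub].reshape(P, D))
                for j in range(G):
                    sp[c, j] = model.subject_prior_param(j, theta[c])
            for h in range(H):
                hp[c, h] = model.hyperprior(h, theta[c])
            total = lik[c].sum() + sp[c].sum() + hp[c].sum()
            if np.isfinite(total):
                break
        else:
            raise RuntimeError("could not find a finite initial state in 100 attempts")

    samples = np.empty((C, config.n_iter, model.n_params))
    acc_sub = np.zeros(2)  # accepted, proposed
    acc_hyp = np.zeros((H, 2))
    acc_mig = np.zeros(2)
    gamma_sub = config.gamma_scale or 2.38 / np.sqrt(2.0 * max(D, 1))

    mig_on = config.migration_interval is not None and config.migration_window is not None

    for it in range(config.n_iter):
        for c in range(C):
            if P > 0:
                # --- all subject blocks at once -------------------------------
                r1 = rng.integers(0, C - 1, P)
                r1 = r1 + (r1 >= c)
                # map r2 into {0..C-1} \ {c, r1}
                r2 = rng.integers(0, C - 2, P)
                lo = np.minimum(c, r1)
                hi = np.maximum(c, r1)
                r2 = r2 + (r2 >= lo)
                r2 = r2 + (r2 >= hi)
                cur = theta[c, :nsub].reshape(P, D)
                g = np.where(rng.random(P) < config.mode_jump_prob, 1.0, gamma_sub)[:, None]
                subj_all = theta[:, :nsub].reshape(C, P, D)
                pidx = np.arange(P)
                diff = subj_all[r1, pidx] - subj_all[r2, pidx]
                prop = cur + g * diff + rng.uniform(-config.jitter, config.jitter, (P, D))
                theta_prop = theta[c].copy()
                theta_prop[:nsub] = prop.ravel()
                prop_lik = model.loglik_subjects(prop)
                if np.isnan(prop_lik).any():
                    raise _nan_error(theta_prop)
                prop_sp = np.vstack([model.subject_prior_param(j, theta_prop) for j in range(G)])
                logr = (prop_lik + prop_sp.sum(0)) - (lik[c] + sp[c].sum(0))
                accept = np.log(rng.random(P)) < logr
                if accept.any():
                    cur[accept] = prop[accept]
                    theta[c, :nsub] = cur.ravel()
                    lik[c, accept] = prop_lik[accept]
                    sp[c][:, accept] = prop_sp[:, accept]
                acc_sub += (accept.sum(), P)
            # --- group-level blocks ------------------------------------------
            for h, blk in enumerate(model.hyper_blocks):
                prop_h = _de_proposal(
                    theta, c, blk.idx, rng, config.gamma_scale, config.mode_jump_prob, config.jitter
                )
                if blk.reflect is not None:
                    prop_h = _reflect(prop_h, *blk.reflect)
                theta_prop = theta[c].copy()
                theta_prop[blk.idx] = prop_h
                new_hp = model.hyperprior(h, theta_prop)
                if np.isnan(new_hp):
                    raise _nan_error(theta_prop)
                new_sp = {j: model.subject_prior_param(j, theta_prop) for j in blk.affected}
                logr = new_hp - hp[c, h]
                for j in blk.affected:
                    logr += new_sp[j].sum() - sp[c, j].sum()
                if np.log(rng.random()) < logr:
                    theta[c, blk.idx] = prop_h
                    hp[c, h] = new_hp
                    for j in blk.affected:
                        sp[c, j] = new_sp[j]
                    acc_hyp[h, 0] += 1
                acc_hyp[h, 1] += 1
        # --- migration -------------------------------------------------------
        if mig_on and config.migration_window[0] <= it <= config.migration_window[1] and (
            it % config.migration_interval == 0
        ):
            full_lp = lik.sum(1) + sp.reshape(C, -1).sum(1) + hp.sum(1)
            k = int(rng.integers(1, C + 1))
            members = rng.choice(C, size=k, replace=False)
            donor_theta = theta[members].copy()
            donor_lik, donor_sp, donor_hp = lik[members].copy(), sp[members].copy(), hp[members].copy()
            donor_lp = full_lp[members].copy()
            for m in range(k):
                recv = members[m]
                if np.log(rng.random()) < donor_lp[m - 1] - full_lp[recv]:
                    theta[recv] = donor_theta[m - 1]
                    lik[recv], sp[recv], hp[recv] = donor_lik[m - 1], donor_sp[m - 1], donor_hp[m - 1]
                    full_lp[recv] = donor_lp[m - 1]
                    acc_mig[0] += 1
                acc_mig[1] += 1
        samples[:, it, :] = theta

    acceptance = {"subjects": _rate(acc_sub)}
    for h, blk in enumerate(model.hyper_blocks):
        acceptance[blk.name] = _rate(acc_hyp[h])
    if acc_mig[1]:
        acceptance["migration"] = _rate(acc_mig)
    return PosteriorSamples(
        samples=samples,
        param_names=list(model.param_names),
        burn_in=config.burn_in,
        acceptance=acceptance,
        config=config,
    )


def _rate(pair):
    return float(pair[0] / pair[1]) if pair[1] else float("nan")


def _reflect(x, lo, hi):
    x = np.asarray(x, dtype=float).copy()
    span = hi - lo
    for i in range(len(x)):
        y = (x[i] - lo) % (2 * span)
        x[i] = lo + (y if y <= span else 2 * span - y)
    return x


def gelman_rubin(samples) -> dict:
    """Classical potential-scale-reduction R-hat per parameter (no chain
    splitting). Accepts PosteriorSamples or a (chains, iters, params) array."""
    if isinstance(samples, PosteriorSamples):
        arr = samples.post_burn()
        names = samples.param_names
    else:
        arr = np.asarray(samples)
        names = list(range(arr.shape[-1]))
    m, n = arr.shape[0], arr.shape[1]
    if m < 2:
        raise ValueError("R-hat needs at least 2 chains")
    if n < 10:
        raise ValueError("R-hat needs at least 10 post-burn iterations")
    chain_means = arr.mean(axis=1)
    chain_vars = arr.var(axis=1, ddof=1)
    W = chain_vars.mean(axis=0)
    B_over_n = chain_means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    # floor at 1: the (n-1)/n shrinkage makes R-hat dip just below 1 when the
    # chains agree (identical chains would otherwise report sqrt((n-1)/n))
    rhat = np.where(W == 0, 1.0, np.maximum(rhat, 1.0))
    return dict(zip(names, rhat))
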