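"""Hierarchical group-difference model for the two-choice diffusion data.

Five subject-level parameters (a, z, ter, v.diff, v.mean) are drawn from
group-level distributions with three hyperparameters each: a population mean
mu, spread sigma, and a group half-difference delta, entering as mu + delta
for the dyslexia group and mu - delta for the typical group (so the
difference in group means is 2*delta, and the plotted/reported "group
difference" is delta itself; negative delta means lower values in the
dyslexia group).

Trials enter the likelihood through the Wiener first-passage density;
non-responses at the deadline contribute the survivor function. Trials with
RT < 200 ms and catch trials are removed before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from motionddm.dists import Dist, norm_logpdf, truncnorm_logpdf
from motionddm.synth import PARAM_NAMES
from motionddm.wfpt import LOGLIK_PENALTY, _loglik_subjects_batch

__all__ = [
    "SubjectParams",
    "GroupHypers",
    "PriorSpec",
    "HyperBlock",
    "HierarchicalDDM",
    "subject_density",
    "log_posterior",
    "filter_trials",
    "two_stage_age_adjust",
]

# supports of the subject-level group distributions
_SUPPORT = {
    "a": (0.0, np.inf),
    "z": (0.0, 1.0),
    "ter": (0.0, np.inf),
    "v.diff": (-np.inf, np.inf),
    "v.mean": (-np.inf, np.inf),
}


@dataclass(frozen=True)
class SubjectParams:
    """One participant's diffusion parameters (v.diff = v_easy - v_hard,
    v.mean = (v_easy + v_hard)/2)."""

    a: float
    z_rel: float
    ter: float
    v_diff: float
    v_mean: float

    @property
    def v_easy(self) -> float:
        return self.v_mean + self.v_diff / 2.0

    @property
    def v_hard(self) -> float:
        return self.v_mean - self.v_diff / 2.0

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.z_rel, self.ter, self.v_diff, self.v_mean])


@dataclass(frozen=True)
class GroupHypers:
    """Per-parameter population mean, spread and group half-difference."""

    mu: dict
    sigma: dict
    delta: dict

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.mu[p], self.sigma[p], self.delta[p]] for p in PARAM_NAMES]
        ).ravel()


def default_priors() -> dict:
    """The model's hyperpriors. Second argument of normal families is an SD;
    Gamma is shape/rate (Gamma(1,1) = Exponential(1))."""
    return {
        "mu": {
            "a": Dist("truncnorm", (0.2, 0.2, 0.0, np.inf)),
            "z": Dist("truncnorm", (0.5, 0.2, 0.0, 1.0)),
            "ter": Dist("truncnorm", (0.3, 0.3, 0.0, np.inf)),
            "v.diff": Dist("normal", (0.0, 0.1)),
            "v.mean": Dist("normal", (0.3, 0.3)),
        },
        "sigma": {p: Dist("gamma", (1.0, 1.0)) for p in PARAM_NAMES},
        "delta": {p: Dist("normal", (0.0, 0.01)) for p in PARAM_NAMES},
    }


@dataclass(frozen=True)
class PriorSpec:
    """Hyperprior specification; defaults to the printed model priors."""

    mu: dict = field(default_factory=lambda: default_priors()["mu"])
    sigma: dict = field(default_factory=lambda: default_priors()["sigma"])
    delta: dict = field(default_factory=lambda: default_priors()["delta"])
    age_beta: Dist = Dist("normal", (0.0, 0.5))


def subject_density(params: SubjectParams, hypers: GroupHypers, group: str) -> float:
    """Log density of one participant's parameters under the group level
    (truncation constants included so each factor normalizes)."""
    if group not in ("typical", "dyslexia"):
        raise ValueError(f"group must be 'typical' or 'dyslexia', got {group!r}")
    c = 1.0 if group == "dyslexia" else -1.0
    x = params.as_array()
    total = 0.0
    for j, p in enumerate(PARAM_NAMES):
        loc = hypers.mu[p] + c * hypers.delta[p]
        sc = hypers.sigma[p]
        if sc <= 0:
            return -np.inf
        lo, hi = _SUPPORT[p]
        if np.isinf(lo) and np.isinf(hi):
            total += float(norm_logpdf(x[j], loc, sc))
        else:
            total += float(truncnorm_logpdf(x[j], loc, sc, lo, hi))
    return total


# ---------------------------------------------------------------------------
# trial filtering
# ---------------------------------------------------------------------------


def filter_trials(raw: pd.DataFrame, rt_floor: float = 0.2):
    """Modelling table: drop responded trials with RT < rt_floor and catch
    trials; keep timeouts as censored records. Returns (table, report)."""
    fast = (~raw["timeout"]) & (raw["rt_s"] < rt_floor)
    catch = raw["catch"].astype(bool)
    kept = raw[~fast & ~catch].reset_index(drop=True)
    rep_rows = []
    for group, sub in raw.groupby("group"):
        f = ((~sub["timeout"]) & (sub["rt_s"] < rt_floor)).sum()
        c = sub["catch"].sum()
        rep_rows.append(
            dict(
                group=group,
                n_raw=len(sub),
                n_fast_removed=int(f),
                pct_fast_removed=100.0 * f / max(len(sub), 1),
                n_catch_removed=int(c),
                n_timeouts=int(sub["timeout"].sum()),
                pct_timeouts=100.0 * sub["timeout"].sum() / max(len(sub), 1),
            )
        )
    return kept, pd.DataFrame(rep_rows)


# ---------------------------------------------------------------------------
# the blocked model (consumed by sampler.run)
# ---------------------------------------------------------------------------


@dataclass
class HyperBlock:
    """A jointly-updated group-level parameter block."""

    name: str
    idx: np.ndarray  # indices into theta
    affected: tuple  # subject-prior columns (j into PARAM_NAMES) it enters
    reflect: tuple | None = None  # optional (lo, hi) reflecting bounds per coord


class HierarchicalDDM:
    """Hierarchical diffusion model over a filtered single-task trial table.

    Parameter vector layout: P subjects x (a, z, ter, v.diff, v.mean), then
    per model parameter a (mu, sigma, delta) triple, then (optionally) one
    age-slope beta per model parameter when `ages` is given (in-model age
    partialling: the group location becomes mu +/- delta + beta*(age - mean age)).
    """

    subject_param_names = PARAM_NAMES

    def __init__(
        self,
        trials: pd.DataFrame,
        priors: PriorSpec | None = None,
        s: float = 0.1,
        deadline: float = 2.5,
        ages: dict | pd.Series | None = None,
        penalty: float = LOGLIK_PENALTY,
        easy_label: str = "easy",
        roster: pd.DataFrame | None = None,
    ):
        if trials["catch"].any():
            raise ValueError("catch trials must be filtered out before fitting")
        if trials["task"].nunique() > 1:
            raise ValueError("fit one task at a time")
        self.priors = priors or PriorSpec()
        self.s, self.deadline, self.penalty = s, deadline, penalty
        if roster is not None:
            # participants may have zero usable trials but still sit in the hierarchy
            self.participants = sorted(roster["participant_id"].unique())
            gmap = roster.drop_duplicates("participant_id").set_index("participant_id")["group"]
        else:
            self.participants = sorted(trials["participant_id"].unique())
            gmap = trials.drop_duplicates("participant_id").set_index("participant_id")["group"]
        self.P = len(self.participants)
        self.group_code = np.array(
            [1.0 if gmap[p] == "dyslexia" else -1.0 for p in self.participants]
        )
        self.age_adjust = ages is not None
        if self.age_adjust:
            ages = pd.Series(ages)
            missing = [p for p in self.participants if p not in ages.index]
            if missing:
                raise ValueError(f"missing ages for participants: {missing}")
            agev = ages.loc[self.participants].to_numpy(dtype=float)
            self.age_c = agev - agev.mean()
        else:
            self.age_c = np.zeros(self.P)

        # flatten trials per participant for the batched likelihood kernel
        rts, rups, touts, signs, easys, offsets = [], [], [], [], [], [0]
        for p in self.participants:
            sub = trials[trials["participant_id"] == p]
            rts.append(np.nan_to_num(sub["rt_s"].to_numpy(dtype=float)))
            rups.append((sub["response"] == "right").to_numpy(dtype=np.uint8))
            touts.append(sub["timeout"].to_numpy(dtype=np.uint8))
            signs.append(np.where(sub["direction"] == "right", 1.0, -1.0))
            easys.append((sub["difficulty"] == easy_label).to_numpy(dtype=np.uint8))
            offsets.append(offsets[-1] + len(sub))
        self._rt = np.concatenate(rts)
        self._rup = np.concatenate(rups)
        self._tout = np.concatenate(touts)
        self._sign = np.concatenate(signs)
        self._easy = np.concatenate(easys)
        self._offsets = np.array(offsets, dtype=np.int64)

        self.subject_dim = 5
        n_sub = self.P * self.subject_dim
        self.hyper_blocks: list[HyperBlock] = []
        names = [f"{p}:{q}" for p in self.participants for q in PARAM_NAMES]
        pos = n_sub
        for j, q in enumerate(PARAM_NAMES):
            names += [f"mu_{q}", f"sigma_{q}", f"delta_{q}"]
            self.hyper_blocks.append(
                HyperBlock(name=q, idx=np.arange(pos, pos + 3), affected=(j,))
            )
            pos += 3
        if self.age_adjust:
            names += [f"beta_age_{q}" for q in PARAM_NAMES]
            self.hyper_blocks.append(
                HyperBlock(name="age_betas", idx=np.arange(pos, pos + 5), affected=tuple(range(5)))
            )
            pos += 5
        self.param_names = names
        self.n_params = pos

    # -- layout helpers ----------------------------------------------------
    def subject_matrix(self, theta: np.ndarray) -> np.ndarray:
        return theta[: self.P * self.subject_dim].reshape(self.P, self.subject_dim)

    def _hyper_triple(self, theta: np.ndarray, j: int):
        base = self.P * self.subject_dim + 3 * j
        return theta[base], theta[base + 1], theta[base + 2]

    def _beta(self, theta: np.ndarray, j: int) -> float:
        if not self.age_adjust:
            return 0.0
        return theta[self.P * self.subject_dim + 15 + j]

    # -- model terms -------------------------------------------------------
    def loglik_subjects(self, subj: np.ndarray) -> np.ndarray:
        """(P,) data log-likelihood per participant."""
        return _loglik_subjects_batch(
            np.ascontiguousarray(subj),
            self._offsets,
            self._rt,
            self._rup,
            self._tout,
            self._sign,
            self._easy,
            self.s,
            self.deadline,
            self.penalty,
        )

    def subject_prior_param(self, j: int, theta: np.ndarray) -> np.ndarray:
        """(P,) group-level log density of subject column j given the hypers."""
        mu, sigma, delta = self._hyper_triple(theta, j)
        if sigma <= 0:
            return np.full(self.P, -np.inf)
        x = self.subject_matrix(theta)[:, j]
        loc = mu + self.group_code * delta + self._beta(theta, j) * self.age_c
        lo, hi = _SUPPORT[PARAM_NAMES[j]]
        if np.isinf(lo) and np.isinf(hi):
            return norm_logpdf(x, loc, sigma)
        return truncnorm_logpdf(x, loc, sigma, lo, hi)

    def hyperprior(self, h: int, theta: np.ndarray) -> float:
        blk = self.hyper_blocks[h]
        if blk.name == "age_betas":
            return float(np.sum(self.priors.age_beta.logpdf(theta[blk.idx])))
        q = blk.name
        mu, sigma, delta = theta[blk.idx]
        return float(
            self.priors.mu[q].logpdf(mu)
            + self.priors.sigma[q].logpdf(sigma)
            + self.priors.delta[q].logpdf(delta)
        )

    def full_logp(self, theta: np.ndarray) -> float:
        """Complete joint log posterior (likelihood + subject priors +
        hyperpriors); reference implementation for tests and migration."""
        subj = self.subject_matrix(theta)
        total = float(np.sum(self.loglik_subjects(subj)))
        for j in range(len(PARAM_NAMES)):
            total += float(np.sum(self.subject_prior_param(j, theta)))
        for h in range(len(self.hyper_blocks)):
            total += self.hyperprior(h, theta)
        return total

    # -- initialization ----------------------------------------------------
    def init_draw(self, rng: np.random.Generator) -> np.ndarray:
        """One chain's initial state: hypers from their priors, subjects from
        the implied group distributions."""
        theta = np.empty(self.n_params)
        base = self.P * self.subject_dim
        for j, q in enumerate(PARAM_NAMES):
            theta[base + 3 * j] = self.priors.mu[q].rvs(rng)
            theta[base + 3 * j + 1] = self.priors.sigma[q].rvs(rng)
            theta[base + 3 * j + 2] = self.priors.delta[q].rvs(rng)
        if self.age_adjust:
            theta[base + 15 : base + 20] = self.priors.age_beta.rvs(rng, 5)
        from scipy import stats

        subj = np.empty((self.P, 5))
        for j, q in enumerate(PARAM_NAMES):
            mu, sigma, delta = self._hyper_triple(theta, j)
            loc = mu + self.group_code * delta + self._beta(theta, j) * self.age_c
            lo, hi = _SUPPORT[q]
            if np.isinf(lo) and np.isinf(hi):
                subj[:, j] = rng.normal(loc, sigma)
            else:
                subj[:, j] = stats.truncnorm.rvs(
                    (lo - loc) / sigma, (hi - loc) / sigma, loc=loc, scale=sigma,
                    random_state=rng,
                )
        theta[: base] = subj.ravel()
        return theta

    def data_informed_draw(self, rng: np.random.Generator) -> np.ndarray:
        """Jittered data-informed start: ter below each subject's fastest RT,
        moderate a and drifts; hypers matched to the subject draws."""
        theta = self.init_draw(rng)
        subj = np.empty((self.P, 5))
        for i in range(self.P):
            lo, hi = self._offsets[i], self._offsets[i + 1]
            rts = self._rt[lo:hi][self._tout[lo:hi] == 0]
            rmin = float(rts.min()) if len(rts) else 0.3
            subj[i] = [
                abs(rng.normal(0.15, 0.03)),
                float(np.clip(rng.normal(0.5, 0.03), 0.05, 0.95)),
                max(rmin * rng.uniform(0.5, 0.9), 0.05),
                rng.normal(0.1, 0.03),
                rng.normal(0.25, 0.08),
            ]
        base = self.P * self.subject_dim
        theta[:base] = subj.ravel()
        for j in range(5):
            theta[base + 3 * j] = float(np.clip(subj[:, j].mean(), *(
                (1e-3, np.inf) if PARAM_NAMES[j] in ("a", "ter") else
                (1e-3, 1 - 1e-3) if PARAM_NAMES[j] == "z" else (-np.inf, np.inf))))
            theta[base + 3 * j + 1] = max(subj[:, j].std(), 0.02) * rng.uniform(0.8, 1.2)
            theta[base + 3 * j + 2] = rng.normal(0.0, 0.005)
        return theta


def log_posterior(
    subject_params: dict,
    hypers: GroupHypers,
    trials: pd.DataFrame,
    priors: PriorSpec | None = None,
    ages: dict | None = None,
    age_betas: dict | None = None,
    s: float = 0.1,
    deadline: float = 2.5,
) -> float:
    """Joint log posterior at explicit parameter values.

    subject_params: {participant_id: SubjectParams}; hypers: GroupHypers.
    Participants in `trials` must exactly match the keys of subject_params.
    """
    model = HierarchicalDDM(trials, priors=priors, s=s, deadline=deadline, ages=ages)
    if set(model.participants) != set(subject_params):
        raise ValueError("participant ids in trials and subject_params differ")
    theta = np.empty(model.n_params)
    for i, p in enumerate(model.participants):
        theta[5 * i : 5 * i + 5] = subject_params[p].as_array()
    base = model.P * 5
    theta[base : base + 15] = hypers.as_array()
    if model.age_adjust:
        betas = [0.0] * 5 if age_betas is None else [age_betas[q] for q in PARAM_NAMES]
        theta[base + 15 : base + 20] = betas
    return model.full_logp(theta)


class _ResidualGroupModel:
    """Tiny normal group-difference model r_p ~ N(mu + c_p*delta, sigma) used
    by the two-stage age-partialling route. Has no subject blocks; the
    residual likelihood lives in the single group-level block."""

    def __init__(self, resid: np.ndarray, group_code: np.ndarray, priors: PriorSpec, param: str):
        self.resid = np.asarray(resid, dtype=float)
        self.group_code = np.asarray(group_code, dtype=float)
        self.priors = priors
        self.param = param
        self.P = 0
        self.subject_dim = 0
        self.n_params = 3
        self.param_names = [f"mu_{param}", f"sigma_{param}", f"delta_{param}"]
        self.hyper_blocks = [HyperBlock(name=param, idx=np.arange(3), affected=())]

    def loglik_subjects(self, subj):  # pragma: no cover - no subject blocks
        return np.zeros(0)

    def subject_prior_param(self, j, theta):  # pragma: no cover
        return np.zeros(0)

    def hyperprior(self, h: int, theta: np.ndarray) -> float:
        mu, sigma, delta = theta
        if sigma <= 0:
            return -np.inf
        q = self.param
        lp = float(
            np.sum(norm_logpdf(self.resid, mu + self.group_code * delta, sigma))
        )
        # residuals are centred, so the location prior is centred at 0 too
        return lp + float(
            norm_logpdf(mu, 0.0, 0.3)
            + self.priors.sigma[q].logpdf(sigma)
            + self.priors.delta[q].logpdf(delta)
        )

    def full_logp(self, theta: np.ndarray) -> float:
        return self.hyperprior(0, theta)

    def init_draw(self, rng: np.random.Generator) -> np.ndarray:
        return np.array(
            [
                rng.normal(0.0, 0.1),
                float(self.priors.sigma[self.param].rvs(rng)),
                float(self.priors.delta[self.param].rvs(rng)),
            ]
        )


def two_stage_age_adjust(samples, model: HierarchicalDDM, ages, sampler_config=None):
    """Two-stage age partialling: regress each subject-level parameter's
    posterior mean on age, then fit a small normal group-difference model
    (mu, sigma, delta with the hierarchical priors) to the residuals.

    Returns {param_name: PosteriorSamples} of the residual models. This is
    the alternative to the in-model age covariate (``ages=`` in
    HierarchicalDDM); both yield a delta posterior.
    """
    from motionddm.sampler import SamplerConfig, run

    ages = pd.Series(ages).loc[model.participants].to_numpy(dtype=float)
    post = samples.post_burn_mean()
    out = {}
    for j, q in enumerate(PARAM_NAMES):
        est = np.array(
            [post[f"{p}:{q}"] for p in model.participants]
        )
        slope, intercept = np.polyfit(ages, est, 1)
        resid = est - (intercept + slope * ages)
        rm = _ResidualGroupModel(resid, model.group_code, model.priors, q)
        cfg = sampler_config or SamplerConfig(n_chains=15, n_iter=1500, burn_in=500, seed=1234 + j)
        out[q] = run(rm, cfg)
    return out
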