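"""Joint modelling of drift-rates and the pre-response EEG slope.

The hierarchical diffusion model is extended so that the population
distributions of v.diff and v.mean become bivariate normals pairing each
with the observed EEG slope measures (EEG.diff = easy - hard slope
difference; EEG.mean = average slope), with correlations rho_diff and
rho_mean estimated either shared across groups or separately per group.
EEG measures are fixed observed data; participants without EEG contribute
through the univariate marginals. Priors: mu_EEG.diff ~ N(0, 0.5),
mu_EEG.mean ~ N(0, 1), sigma_EEG ~ Gamma(1,1), delta_EEG ~ N(0, 0.01),
rho ~ U(-1, 1); the Savage-Dickey prior density at rho = 0 is exactly 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from motionddm.dists import Dist, norm_logpdf
from motionddm.hierarchy import GroupHypers, HierarchicalDDM, HyperBlock, PriorSpec
from motionddm.inference import BFResult, savage_dickey
from motionddm.sampler import PosteriorSamples, SamplerConfig, run
from motionddm.synth import PARAM_NAMES

__all__ = ["JointHypers", "JointDDM", "joint_density", "fit_joint", "rho_bayes_factor"]

_PAIRS = (("diff", 3), ("mean", 4))  # EEG measure <-> subject column it couples to


@dataclass(frozen=True)
class JointHypers:
    """Population-level parameters of the EEG side of the joint model."""

    mu_eeg_mean: float
    mu_eeg_diff: float
    sigma_eeg_mean: float
    sigma_eeg_diff: float
    delta_eeg_mean: float = 0.0
    delta_eeg_diff: float = 0.0
    rho_mean: float = 0.0
    rho_diff: float = 0.0

    def __post_init__(self):
        if self.sigma_eeg_mean <= 0 or self.sigma_eeg_diff <= 0:
            raise ValueError("sigma values must be > 0")
        if not (-1 < self.rho_mean < 1 and -1 < self.rho_diff < 1):
            raise ValueError("rho must be in (-1, 1)")


def default_joint_priors() -> dict:
    return {
        "mu": {"mean": Dist("normal", (0.0, 1.0)), "diff": Dist("normal", (0.0, 0.5))},
        "sigma": {m: Dist("gamma", (1.0, 1.0)) for m in ("mean", "diff")},
        "delta": {m: Dist("normal", (0.0, 0.01)) for m in ("mean", "diff")},
        "rho": Dist("uniform", (-1.0, 1.0)),
    }


def _bvn_logpdf(x, y, loc_x, loc_y, sx, sy, rho):
    """Bivariate normal log density, vectorized over observations."""
    zx = (x - loc_x) / sx
    zy = (y - loc_y) / sy
    om = 1.0 - rho * rho
    return (
        -math.log(2.0 * math.pi)
        - np.log(sx * sy)
        - 0.5 * np.log(om)
        - (zx * zx - 2.0 * rho * zx * zy + zy * zy) / (2.0 * om)
    )


def joint_density(
    v_mean: float,
    v_diff: float,
    eeg_mean: float,
    eeg_diff: float,
    hypers: GroupHypers,
    joint_hypers: JointHypers,
    group: str,
) -> float:
    """Log density of the drift/EEG block for one participant: two bivariate
    normals, (v.mean, EEG.mean) and (v.diff, EEG.diff), with mu +/- delta
    group locations. Other model parameters are untouched by the joint
    extension."""
    if group not in ("typical", "dyslexia"):
        raise ValueError("group must be 'typical' or 'dyslexia'")
    c = 1.0 if group == "dyslexia" else -1.0
    jh = joint_hypers
    out = _bvn_logpdf(
        v_mean,
        eeg_mean,
        hypers.mu["v.mean"] + c * hypers.delta["v.mean"],
        jh.mu_eeg_mean + c * jh.delta_eeg_mean,
        hypers.sigma["v.mean"],
        jh.sigma_eeg_mean,
        jh.rho_mean,
    )
    out = out + _bvn_logpdf(
        v_diff,
        eeg_diff,
        hypers.mu["v.diff"] + c * hypers.delta["v.diff"],
        jh.mu_eeg_diff + c * jh.delta_eeg_diff,
        hypers.sigma["v.diff"],
        jh.sigma_eeg_diff,
        jh.rho_diff,
    )
    return float(out)


class JointDDM(HierarchicalDDM):
    """Hierarchical diffusion model with bivariate (drift, EEG-slope)
    population distributions.

    `slopes`: DataFrame with participant_id and either (eeg_mean, eeg_diff)
    or (slope_easy, slope_hard). Participants present in the trial table but
    absent from `slopes` are kept and contribute through the univariate
    marginals. variant: 'shared_rho' or 'group_rho'.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        slopes: pd.DataFrame,
        variant: str = "shared_rho",
        priors: PriorSpec | None = None,
        joint_priors: dict | None = None,
        ages=None,
        **kwargs,
    ):
        super().__init__(trials, priors=priors, ages=ages, **kwargs)
        if variant not in ("shared_rho", "group_rho"):
            raise ValueError("variant must be 'shared_rho' or 'group_rho'")
        self.variant = variant
        self.joint_priors = joint_priors or default_joint_priors()

        sl = slopes.set_index("participant_id")
        if "eeg_mean" not in sl.columns:
            sl = sl.assign(
                eeg_mean=0.5 * (sl["slope_easy"] + sl["slope_hard"]),
                eeg_diff=sl["slope_easy"] - sl["slope_hard"],
            )
        self.eeg = {}
        for m, _ in _PAIRS:
            self.eeg[m] = np.array(
                [
                    float(sl.loc[p, f"eeg_{m}"]) if p in sl.index else np.nan
                    for p in self.participants
                ]
            )
        if np.all(np.isnan(self.eeg["mean"])):
            raise ValueError("no participants with EEG measures")

        # extend the parameter vector: EEG hyper triples, then rho block(s)
        pos = self.n_params
        for m, j in _PAIRS:
            self.param_names += [f"mu_EEG.{m}", f"sigma_EEG.{m}", f"delta_EEG.{m}"]
            self.hyper_blocks.append(
                HyperBlock(name=f"EEG.{m}", idx=np.arange(pos, pos + 3), affected=(j,))
            )
            pos += 3
        self._rho_idx = {}
        for m, j in _PAIRS:
            width = 1 if variant == "shared_rho" else 2
            names = (
                [f"rho_{m}"]
                if variant == "shared_rho"
                else [f"rho_{m}_typical", f"rho_{m}_dyslexia"]
            )
            self.param_names += names
            self.hyper_blocks.append(
                HyperBlock(
                    name=f"rho_{m}",
                    idx=np.arange(pos, pos + width),
                    affected=(j,),
                    reflect=(-1.0, 1.0),
                )
            )
            self._rho_idx[m] = np.arange(pos, pos + width)
            pos += width
        self._hier_n = pos - 6 - sum(len(self._rho_idx[m]) for m, _ in _PAIRS)
        self.n_params = pos
        self._eeg_base = {m: self.hyper_blocks[-4 + i].idx[0] for i, (m, _) in enumerate(_PAIRS)}

    # -- overrides ---------------------------------------------------------
    def _rho_per_subject(self, theta, m):
        idx = self._rho_idx[m]
        if self.variant == "shared_rho":
            return np.full(self.P, theta[idx[0]])
        # group-specific: typical first, dyslexia second
        return np.where(self.group_code > 0, theta[idx[1]], theta[idx[0]])

    def subject_prior_param(self, j: int, theta: np.ndarray) -> np.ndarray:
        pair = {jj: m for m, jj in _PAIRS}
        if j not in pair:
            return super().subject_prior_param(j, theta)
        m = pair[j]
        mu, sigma, delta = self._hyper_triple(theta, j)
        base = self._eeg_base[m]
        mu_e, sigma_e, delta_e = theta[base], theta[base + 1], theta[base + 2]
        rho = self._rho_per_subject(theta, m)
        if sigma <= 0 or sigma_e <= 0 or np.any(np.abs(rho) >= 1):
            return np.full(self.P, -np.inf)
        x = self.subject_matrix(theta)[:, j]
        loc_v = mu + self.group_code * delta + self._beta(theta, j) * self.age_c
        loc_e = mu_e + self.group_code * delta_e
        e = self.eeg[m]
        have = ~np.isnan(e)
        out = np.empty(self.P)
        out[~have] = norm_logpdf(x[~have], loc_v[~have] if np.ndim(loc_v) else loc_v, sigma)
        out[have] = _bvn_logpdf(
            x[have], e[have], np.broadcast_to(loc_v, x.shape)[have],
            np.broadcast_to(loc_e, x.shape)[have], sigma, sigma_e, rho[have],
        )
        return out

    def hyperprior(self, h: int, theta: np.ndarray) -> float:
        blk = self.hyper_blocks[h]
        if blk.name.startswith("EEG."):
            m = blk.name.split(".")[1]
            mu, sigma, delta = theta[blk.idx]
            return float(
                self.joint_priors["mu"][m].logpdf(mu)
                + self.joint_priors["sigma"][m].logpdf(sigma)
                + self.joint_priors["delta"][m].logpdf(delta)
            )
        if blk.name.startswith("rho_"):
            return float(np.sum(self.joint_priors["rho"].logpdf(theta[blk.idx])))
        return super().hyperprior(h, theta)

    def init_draw(self, rng: np.random.Generator) -> np.ndarray:
        # the parent draw allocates the full (extended) vector and fills the
        # hierarchical positions; fill the EEG extension here
        theta = super().init_draw(rng)
        pos = self._hier_n
        for m, _ in _PAIRS:
            e = self.eeg[m]
            have = ~np.isnan(e)
            theta[pos] = float(np.mean(e[have]) + rng.normal(0, 0.5))
            theta[pos + 1] = max(float(np.std(e[have]) * rng.uniform(0.5, 1.5)), 0.1)
            theta[pos + 2] = float(self.joint_priors["delta"][m].rvs(rng))
            pos += 3
        for m, _ in _PAIRS:
            width = len(self._rho_idx[m])
            theta[pos : pos + width] = self.joint_priors["rho"].rvs(rng, width)
            pos += width
        return theta


def fit_joint(
    trials: pd.DataFrame,
    slopes: pd.DataFrame,
    variant: str = "shared_rho",
    config: SamplerConfig | None = None,
    priors: PriorSpec | None = None,
    joint_priors: dict | None = None,
    ages=None,
    **model_kwargs,
):
    """Fit the joint model with DE-MCMC (default: 15 chains, 3000 iterations,
    1000 burn-in, no migration) and summarize the rho posteriors.

    Returns (samples, model, rho_table) where rho_table has one row per rho
    parameter with posterior mean, central 95% CI and Savage-Dickey BF
    against rho = 0 (prior density 0.5 exactly).
    """
    model = JointDDM(
        trials, slopes, variant=variant, priors=priors, joint_priors=joint_priors,
        ages=ages, **model_kwargs,
    )
    config = config or SamplerConfig(
        n_chains=15, n_iter=3000, burn_in=1000,
        migration_interval=None, migration_window=None, init="data",
    )
    samples = run(model, config)
    rows = []
    for name in model.param_names:
        if not name.startswith("rho_"):
            continue
        draws = samples.get(name)
        bf = rho_bayes_factor(draws, model.joint_priors["rho"], name)
        rows.append(
            dict(
                parameter=name,
                mean=float(draws.mean()),
                ci_low=float(np.percentile(draws, 2.5)),
                ci_high=float(np.percentile(draws, 97.5)),
                bf10=bf.bf10,
            )
        )
    return samples, model, pd.DataFrame(rows)


def rho_bayes_factor(rho_samples: np.ndarray, prior: Dist | None = None, name: str = "rho") -> BFResult:
    """Savage-Dickey BF for rho = 0; the U(-1,1) prior density at 0 is 0.5."""
    return savage_dickey(rho_samples, prior or Dist("uniform", (-1.0, 1.0)), parameter=name)
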