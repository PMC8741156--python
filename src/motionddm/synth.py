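"""Synthetic study generator.

Emulates the structure of a two-group (dyslexia / typical) developmental
study of two-choice global-motion discrimination: 2 tasks (motion coherence,
direction integration), 4 experimental blocks per task, each block holding
9 repetitions x 2 difficulty levels x 2 motion directions plus 2 catch
trials (38 trials/block, 152 trials/task), a 2500 ms response deadline that
produces occasional non-responses, and continuous EEG in which
stimulus-locked and response-locked kernels overlap, with the response
kernel's pre-response slope linearly tied to the participant's mean
drift-rate.

Behavioural RTs are drawn from the Wiener first-passage process (module
``wfpt``), with subject-level diffusion parameters drawn from group-level
distributions under the mu +/- delta convention (dyslexia = mu + delta,
typical = mu - delta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from motionddm.io import EEGRecording, TRIAL_COLUMNS
from motionddm.wfpt import _simulate_batch

__all__ = [
    "StudyDesign",
    "GeneratorConfig",
    "generate_behaviour",
    "plant_slopes",
    "generate_eeg",
    "block_points",
    "PARAM_NAMES",
]

PARAM_NAMES = ("a", "z", "ter", "v.diff", "v.mean")

TASKS = ("motion_coherence", "direction_integration")


@dataclass(frozen=True)
class StudyDesign:
    """Block/trial structure of the study."""

    n_per_group: int = 12
    tasks: tuple[str, ...] = TASKS
    blocks_per_task: int = 4
    reps_per_cell: int = 9
    difficulty_levels: tuple[str, str] = ("easy", "hard")
    catch_per_block: int = 2
    deadline: float = 2.5
    rt_floor: float = 0.2
    # (min, max) seconds for the jittered fixation / random-motion / offset periods
    jitter_fixation: tuple[float, float] = (1.0, 1.5)
    jitter_random_motion: tuple[float, float] = (1.0, 1.5)
    jitter_offset: tuple[float, float] = (0.25, 0.5)

    def __post_init__(self) -> None:
        for name in ("n_per_group", "blocks_per_task", "reps_per_cell", "catch_per_block"):
            if getattr(self, name) < 0 or (name != "catch_per_block" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if self.deadline <= 0:
            raise ValueError("deadline must be positive")

    @property
    def trials_per_block(self) -> int:
        return self.reps_per_cell * 2 * 2 + self.catch_per_block

    @property
    def trials_per_task(self) -> int:
        return self.blocks_per_task * self.trials_per_block


# Group-level truth used by the generator. mu values sit at the centres of
# the hierarchical model's hyperpriors (a=0.2, z=0.5, ter=0.3, v.mean=0.3)
# except v.diff, whose hyperprior is centred at 0 but which is given a
# positive default so the two difficulty levels actually differ. sigma values
# are typical between-child spreads in the s=0.1 evidence convention.
_DEFAULT_MU = {"a": 0.2, "z": 0.5, "ter": 0.3, "v.diff": 0.1, "v.mean": 0.3}
_DEFAULT_SIGMA = {"a": 0.04, "z": 0.05, "ter": 0.05, "v.diff": 0.04, "v.mean": 0.06}
_DEFAULT_DELTA = {p: 0.0 for p in PARAM_NAMES}


@dataclass(frozen=True)
class EEGLink:
    """Linear link from drift-rate to the response-kernel slope:
    slope_{p,d} = alpha0 + alpha1 * v_{p,d} + residual, residual ~ N(0, resid_sd),
    drawn independently per difficulty level. Units: microvolts/second.
    Defaults target corr(v.mean, EEG.mean) = 0.44 at the default drift spread."""

    alpha0: float = 5.0
    alpha1: float = 22.0
    resid_sd: float = 3.81

    @classmethod
    def for_target_rho(cls, rho: float, sigma_v: float, sigma_slope: float = 3.0, alpha0: float = 5.0) -> "EEGLink":
        """Choose (alpha1, resid_sd) so that corr(v.mean, EEG.mean) = rho in
        the population, where EEG.mean averages the two per-difficulty slopes
        (its residual SD is resid_sd/sqrt(2)); sigma_slope sets the total
        EEG.mean spread, sigma_v the between-subject v.mean SD."""
        if not (-1.0 < rho < 1.0):
            raise ValueError("rho must be in (-1, 1)")
        alpha1 = rho * sigma_slope / sigma_v
        resid_sd = sigma_slope * math.sqrt(2.0 * (1.0 - rho * rho))
        return cls(alpha0=alpha0, alpha1=alpha1, resid_sd=resid_sd)


@dataclass(frozen=True)
class GeneratorConfig:
    """Planted truth and noise model for the generator."""

    mu: dict = field(default_factory=lambda: dict(_DEFAULT_MU))
    sigma: dict = field(default_factory=lambda: dict(_DEFAULT_SIGMA))
    delta: dict = field(default_factory=lambda: dict(_DEFAULT_DELTA))
    s: float = 0.1
    eeg_link: EEGLink = field(default_factory=EEGLink)
    ar_coef: float = 0.95
    noise_sd: float = 10.0  # stationary AR(1) SD, microvolts
    n_channels: int = 1
    topography: tuple[float, ...] | None = None
    sfreq: float = 250.0
    fast_guess_frac: float = 0.0  # contaminant trials with uniform RT in [0, 0.3] s
    catch_drift_multiplier: float = 2.0
    sim_dt: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.sigma.values()):
            raise ValueError("all sigma values must be > 0")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be > 0")
        if not (-1.0 < self.ar_coef < 1.0):
            raise ValueError("AR(1) coefficient must be in (-1, 1)")
        if not (0.0 <= self.fast_guess_frac < 1.0):
            raise ValueError("fast_guess_frac must be in [0, 1)")


def _draw_subject_params(config: GeneratorConfig, group: str, rng: np.random.Generator) -> dict:
    """Draw one participant's diffusion parameters from the group level
    (mu + delta for dyslexia, mu - delta for typical; truncated supports)."""
    c = 1.0 if group == "dyslexia" else -1.0
    out = {}
    for p in PARAM_NAMES:
        loc = config.mu[p] + c * config.delta[p]
        sc = config.sigma[p]
        if p == "a" or p == "ter":
            lo, hi = 0.0, np.inf
        elif p == "z":
            lo, hi = 0.0, 1.0
        else:
            lo, hi = -np.inf, np.inf
        a_, b_ = (lo - loc) / sc, (hi - loc) / sc
        out[p] = float(stats.truncnorm.rvs(a_, b_, loc=loc, scale=sc, random_state=rng))
    return out


def generate_behaviour(design: StudyDesign, config: GeneratorConfig):
    """Generate the behavioural trial table and the true subject parameters.

    Returns (trials, truth): `trials` has the standard trial-table columns,
    `truth` one row per participant x task with the generating parameters.
    All randomness flows from config.seed through per-participant substreams.
    """
    root = np.random.SeedSequence(config.seed)
    groups = ["dyslexia"] * design.n_per_group + ["typical"] * design.n_per_group
    pids = [f"d{i+1:02d}" for i in range(design.n_per_group)] + [
        f"t{i+1:02d}" for i in range(design.n_per_group)
    ]
    subject_seeds = root.spawn(len(pids))

    rows = []
    truth_rows = []
    for pid, group, sseq in zip(pids, groups, subject_seeds):
        for task, tseq in zip(design.tasks, sseq.spawn(len(design.tasks))):
            rng = np.random.default_rng(tseq)
            par = _draw_subject_params(config, group, rng)
            v_easy = par["v.mean"] + par["v.diff"] / 2.0
            v_hard = par["v.mean"] - par["v.diff"] / 2.0
            truth_rows.append(
                dict(
                    participant_id=pid, group=group, task=task,
                    a=par["a"], z=par["z"], ter=par["ter"],
                    **{"v.diff": par["v.diff"], "v.mean": par["v.mean"]},
                    v_easy=v_easy, v_hard=v_hard,
                )
            )
            # build the per-block trial lists
            diff_labels, signs, is_catch = [], [], []
            for _ in range(design.blocks_per_task):
                blk_diff = (
                    [design.difficulty_levels[0], design.difficulty_levels[1]]
                    * 2 * design.reps_per_cell
                )
                blk_sign = ([1.0] * design.reps_per_cell + [-1.0] * design.reps_per_cell) * 2
                blk_catch = [False] * (4 * design.reps_per_cell)
                for _c in range(design.catch_per_block):
                    blk_diff.append("catch")
                    blk_sign.append(1.0 if rng.random() < 0.5 else -1.0)
                    blk_catch.append(True)
                order = rng.permutation(len(blk_diff))
                diff_labels.extend([blk_diff[i] for i in order])
                signs.extend([blk_sign[i] for i in order])
                is_catch.extend([blk_catch[i] for i in order])
            signs = np.asarray(signs)
            v_level = np.where(
                np.asarray(diff_labels) == design.difficulty_levels[0], v_easy,
                np.where(np.asarray(diff_labels) == "catch",
                         config.catch_drift_multiplier * v_easy, v_hard),
            )
            v_trial = signs * v_level
            seed = int(rng.integers(0, 2**31 - 1))
            rt, out = _simulate_batch(
                v_trial, par["a"], par["z"], par["ter"], config.s,
                design.deadline, config.sim_dt, seed,
            )
            # optional fast-guess contaminants on non-catch trials
            if config.fast_guess_frac > 0:
                contam = (rng.random(len(v_trial)) < config.fast_guess_frac) & ~np.asarray(is_catch)
                rt = rt.copy(); out = out.copy()
                rt[contam] = rng.uniform(0.0, 0.3, contam.sum())
                out[contam] = (rng.random(contam.sum()) < 0.5).astype(np.int8)
            # lay trials on a common clock
            t_clock = 0.0
            for i in range(len(v_trial)):
                t_clock += rng.uniform(*design.jitter_fixation)
                t_clock += rng.uniform(*design.jitter_random_motion)
                stim_t = t_clock
                timeout = out[i] == -1
                resp = "timeout" if timeout else ("right" if out[i] == 1 else "left")
                rti = np.nan if timeout else float(rt[i])
                resp_t = np.nan if timeout else stim_t + rti
                t_clock = stim_t + (design.deadline if timeout else rti)
                t_clock += rng.uniform(*design.jitter_offset)
                rows.append(
                    dict(
                        participant_id=pid, group=group, task=task,
                        block=i // design.trials_per_block + 1, trial=i + 1,
                        difficulty=diff_labels[i],
                        direction="right" if signs[i] > 0 else "left",
                        response=resp, rt_s=rti, timeout=bool(timeout),
                        catch=bool(is_catch[i]),
                        stim_time_s=stim_t, resp_time_s=resp_t,
                    )
                )
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return trials, truth


def plant_slopes(truth: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Add planted response-kernel slopes (microvolts/s) per difficulty level
    to a truth table, using the configured drift -> slope link."""
    link = config.eeg_link
    out = truth.copy()
    out["slope_easy"] = (
        link.alpha0 + link.alpha1 * out["v_easy"].to_numpy()
        + rng.normal(0.0, link.resid_sd, len(out))
    )
    out["slope_hard"] = (
        link.alpha0 + link.alpha1 * out["v_hard"].to_numpy()
        + rng.normal(0.0, link.resid_sd, len(out))
    )
    return out


def _stimulus_kernel(sfreq: float, difficulty: str) -> np.ndarray:
    """Fixed stimulus-locked kernel, 0..600 ms: an early biphasic visual
    deflection plus a sustained bump whose amplitude depends on difficulty."""
    n = int(round(0.6 * sfreq))
    t = np.arange(n) / sfreq
    amp = 5.0 if difficulty == "easy" else 4.0
    early = 3.0 * np.sin(2 * np.pi * t / 0.2) * np.exp(-t / 0.12)
    late = amp * np.hanning(n)
    return early + late


def _response_kernel(sfreq: float, slope: float) -> tuple[np.ndarray, int]:
    """Response-locked kernel: linear ramp over the 400 ms before the
    response with the given slope (microvolts/s). Returns (kernel, offset)
    where offset is the kernel start relative to the event, in samples."""
    n = int(round(0.4 * sfreq)) + 1
    tau = np.arange(n) / sfreq - 0.4
    return slope * (tau + 0.4), -int(round(0.4 * sfreq))


def generate_eeg(
    trials: pd.DataFrame,
    slopes: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> EEGRecording:
    """Synthesize one participant-task continuous EEG recording.

    signal = sum of stimulus-locked kernels + sum of response-locked kernels
    + AR(1) noise. The response kernel is a linear ramp over the 400 ms
    before the response whose slope is the participant's planted slope for
    that difficulty level. `trials` must be a single participant x task
    subset; `slopes` the matching truth row (with slope_easy / slope_hard).
    """
    if trials["participant_id"].nunique() != 1 or trials["task"].nunique() != 1:
        raise ValueError("generate_eeg expects a single participant x task trial subset")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    row = slopes.iloc[0]
    sfreq = config.sfreq
    if (trials["resp_time_s"].dropna() < trials["stim_time_s"][trials["resp_time_s"].notna()]).any():
        raise ValueError("response before stimulus")
    t_end = float(
        np.nanmax(
            np.concatenate(
                [trials["stim_time_s"].to_numpy() + 3.0, trials["resp_time_s"].to_numpy()[None].ravel() + 2.0]
            )
        )
    )
    n_samp = int(round(t_end * sfreq))
    comp = np.zeros(n_samp)
    events: list[dict] = []

    def _add(kernel: np.ndarray, start: int) -> None:
        lo, hi = max(start, 0), min(start + len(kernel), n_samp)
        if hi > lo:
            comp[lo:hi] += kernel[lo - start : hi - start]

    last_sample = -10
    for _, tr in trials.iterrows():
        diff = tr["difficulty"]
        stim_samp = int(round(tr["stim_time_s"] * sfreq))
        if stim_samp <= last_sample:
            raise ValueError("events closer together than one sample")
        last_sample = stim_samp
        _add(_stimulus_kernel(sfreq, "easy" if diff == "catch" else diff), stim_samp)
        events.append({"time_s": stim_samp / sfreq, "type": "stimulus", "difficulty": diff})
        if not tr["timeout"]:
            slope = float(row["slope_easy"] if diff in ("easy", "catch") else row["slope_hard"])
            resp_samp = int(round(tr["resp_time_s"] * sfreq))
            if resp_samp <= stim_samp:
                raise ValueError("response before stimulus")
            kern, off = _response_kernel(sfreq, slope)
            _add(kern, resp_samp + off)
            events.append({"time_s": resp_samp / sfreq, "type": "response", "difficulty": diff})
            last_sample = resp_samp

    if config.noise_sd > 0:
        from scipy.signal import lfilter

        eps_sd = config.noise_sd * math.sqrt(1.0 - config.ar_coef**2)
        eps = rng.normal(0.0, eps_sd, n_samp)
        x0 = rng.normal(0.0, config.noise_sd)
        noise = lfilter([1.0], [1.0, -config.ar_coef], eps, zi=[config.ar_coef * x0])[0]
        comp = comp + noise

    if config.n_channels > 1:
        topo = (
            np.asarray(config.topography, dtype=float)
            if config.topography is not None
            else np.hanning(config.n_channels + 2)[1:-1]
        )
        data = np.outer(topo, comp)
        if config.noise_sd > 0:
            data = data + rng.normal(0.0, config.noise_sd * 0.5, data.shape)
    else:
        data = comp[None, :]
    return EEGRecording(data=data, sfreq=sfreq, events=events)


def block_points(median_rt: float, n_correct: int) -> int:
    """Per-block motivation score: round((1 / median RT) * n_correct * 2) to
    the nearest integer; scores under 10 are replaced by 10."""
    if median_rt <= 0:
        raise ValueError("median_rt must be > 0")
    raw = int(np.rint(n_correct * 2.0 / median_rt))
    return max(raw, 10)
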