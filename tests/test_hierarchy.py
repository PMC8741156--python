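"""Hierarchical model: group-level densities, filtering, age adjustment."""

import numpy as np
import pandas as pd
import pytest

from motionddm.hierarchy import (
    GroupHypers,
    HierarchicalDDM,
    PriorSpec,
    SubjectParams,
    filter_trials,
    log_posterior,
    subject_density,
)
from motionddm.synth import PARAM_NAMES, GeneratorConfig, StudyDesign, generate_behaviour
from motionddm.wfpt import trial_loglik
from oracles import scalar_subject_logdensity

HYPERS = GroupHypers(
    mu={"a": 0.2, "z": 0.5, "ter": 0.3, "v.diff": 0.1, "v.mean": 0.3},
    sigma={"a": 0.05, "z": 0.05, "ter": 0.05, "v.diff": 0.05, "v.mean": 0.08},
    delta={"a": 0.0, "z": 0.0, "ter": 0.0, "v.diff": 0.0, "v.mean": -0.02},
)
PARAMS = SubjectParams(a=0.18, z_rel=0.52, ter=0.33, v_diff=0.08, v_mean=0.25)


class TestSubjectDensity:
    def test_matches_scipy_scalar_oracle(self):
        for group in ("typical", "dyslexia"):
            ours = subject_density(PARAMS, HYPERS, group)
            oracle = scalar_subject_logdensity(PARAMS, HYPERS, group)
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_symmetric_under_group_swap_when_delta_zero(self):
        h0 = GroupHypers(mu=HYPERS.mu, sigma=HYPERS.sigma, delta={p: 0.0 for p in PARAM_NAMES})
        assert subject_density(PARAMS, h0, "typical") == subject_density(PARAMS, h0, "dyslexia")

    def test_out_of_support_is_minus_inf(self):
        bad = SubjectParams(a=-0.1, z_rel=0.5, ter=0.3, v_diff=0.0, v_mean=0.3)
        assert subject_density(bad, HYPERS, "typical") == -np.inf

    def test_drift_parameterization_roundtrip(self):
        assert PARAMS.v_easy - PARAMS.v_hard == pytest.approx(PARAMS.v_diff)
        assert 0.5 * (PARAMS.v_easy + PARAMS.v_hard) == pytest.approx(PARAMS.v_mean)


@pytest.fixture(scope="module")
def tiny_fit_data():
    design = StudyDesign(n_per_group=1, blocks_per_task=1, tasks=("motion_coherence",))
    trials, _ = generate_behaviour(design, GeneratorConfig(seed=42))
    kept, _ = filter_trials(trials)
    return kept


class TestLogPosterior:
    def _subject_params(self, kept):
        return {p: PARAMS for p in kept.participant_id.unique()}

    def test_equals_sum_of_parts_on_two_participant_fixture(self, tiny_fit_data):
        kept = tiny_fit_data
        sp = self._subject_params(kept)
        total = log_posterior(sp, HYPERS, kept)
        # independent reassembly: trial term + subject priors + hyperpriors
        priors = PriorSpec()
        expected = 0.0
        from motionddm.wfpt import DiffusionParams

        for pid, par in sp.items():
            sub = kept[kept.participant_id == pid]
            group = sub.group.iloc[0]
            for _, tr in sub.iterrows():
                v = par.v_easy if tr.difficulty == "easy" else par.v_hard
                sign = 1.0 if tr.direction == "right" else -1.0
                dp = DiffusionParams(a=par.a, z_rel=par.z_rel, ter=par.ter, v=sign * v)
                if tr.timeout:
                    expected += trial_loglik(None, None, True, dp)
                else:
                    expected += trial_loglik(
                        tr.rt_s, "upper" if tr.response == "right" else "lower", False, dp
                    )
            expected += scalar_subject_logdensity(par, HYPERS, group)
        for q in PARAM_NAMES:
            expected += float(priors.mu[q].logpdf(HYPERS.mu[q]))
            expected += float(priors.sigma[q].logpdf(HYPERS.sigma[q]))
            expected += float(priors.delta[q].logpdf(HYPERS.delta[q]))
        assert total == pytest.approx(expected, rel=1e-9)

    def test_duplicated_trial_adds_exactly_its_loglik(self, tiny_fit_data):
        kept = tiny_fit_data
        sp = self._subject_params(kept)
        base = log_posterior(sp, HYPERS, kept)
        responded = kept[~kept.timeout]
        dup = pd.concat([kept, responded.iloc[[0]]], ignore_index=True)
        tr = responded.iloc[0]
        par = sp[tr.participant_id]
        from motionddm.wfpt import DiffusionParams

        v = par.v_easy if tr.difficulty == "easy" else par.v_hard
        sign = 1.0 if tr.direction == "right" else -1.0
        dp = DiffusionParams(a=par.a, z_rel=par.z_rel, ter=par.ter, v=sign * v)
        extra = trial_loglik(tr.rt_s, "upper" if tr.response == "right" else "lower", False, dp)
        assert log_posterior(sp, HYPERS, dup) == pytest.approx(base + extra, rel=1e-9)

    def test_empty_dataset_leaves_prior_terms_only(self, tiny_fit_data):
        kept = tiny_fit_data
        roster = kept[["participant_id", "group"]].drop_duplicates()
        empty = kept.iloc[0:0]
        model = HierarchicalDDM(empty, roster=roster)
        theta = np.empty(model.n_params)
        for i, p in enumerate(model.participants):
            theta[5 * i : 5 * i + 5] = PARAMS.as_array()
        theta[model.P * 5 :] = HYPERS.as_array()
        expected = 0.0
        priors = PriorSpec()
        for p in model.participants:
            g = roster.set_index("participant_id").group[p]
            expected += scalar_subject_logdensity(PARAMS, HYPERS, g)
        for q in PARAM_NAMES:
            expected += float(priors.mu[q].logpdf(HYPERS.mu[q]))
            expected += float(priors.sigma[q].logpdf(HYPERS.sigma[q]))
            expected += float(priors.delta[q].logpdf(HYPERS.delta[q]))
        assert model.full_logp(theta) == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_participant_relabelling(self, tiny_fit_data):
        kept = tiny_fit_data
        sp = self._subject_params(kept)
        base = log_posterior(sp, HYPERS, kept)
        shuffled = kept.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert log_posterior(sp, HYPERS, shuffled) == pytest.approx(base, rel=1e-12)

    def test_pooled_model_recovered_when_delta_zero(self, tiny_fit_data):
        kept = tiny_fit_data
        sp = self._subject_params(kept)
        h0 = GroupHypers(mu=HYPERS.mu, sigma=HYPERS.sigma, delta={p: 0.0 for p in PARAM_NAMES})
        grouped = log_posterior(sp, h0, kept)
        pooled_tbl = kept.assign(group="typical")
        pooled = log_posterior(sp, h0, pooled_tbl)
        assert grouped == pytest.approx(pooled, rel=1e-12)


class TestFilterTrials:
    def test_fast_trial_excluded_and_counted(self, tiny_fit_data):
        base = tiny_fit_data.copy()
        fast = base.iloc[[0]].assign(rt_s=0.15, timeout=False)
        table = pd.concat([base, fast], ignore_index=True)
        kept, report = filter_trials(table)
        assert len(kept) == len(base)
        assert report.n_fast_removed.sum() == 1

    def test_all_timeout_table_untouched_by_rt_filter(self):
        t = pd.DataFrame(
            dict(participant_id=["p1"] * 3, group="typical", task="motion_coherence",
                 block=1, trial=[1, 2, 3], difficulty="easy", direction="right",
                 response="timeout", rt_s=np.nan, timeout=True, catch=False,
                 stim_time_s=[1.0, 5.0, 9.0], resp_time_s=np.nan)
        )
        kept, report = filter_trials(t)
        assert len(kept) == 3
        assert report.n_fast_removed.sum() == 0

    def test_injected_fast_guess_rate_recovered(self):
        frac = 0.05
        d = StudyDesign(n_per_group=4, tasks=("motion_coherence",))
        cfg = GeneratorConfig(seed=21, fast_guess_frac=frac)
        trials, _ = generate_behaviour(d, cfg)
        _, report = filter_trials(trials)
        noncatch = (~trials.catch).sum()
        # fast guesses are uniform on [0, 0.3]; 2/3 fall under the 200 ms floor
        expected = frac * (0.2 / 0.3)
        obs = report.n_fast_removed.sum() / noncatch
        se = np.sqrt(expected * (1 - expected) / noncatch)
        assert abs(obs - expected) < 3 * se


class TestAgeAdjustment:
    def test_equal_ages_reduce_to_unadjusted_model(self, tiny_fit_data):
        kept = tiny_fit_data
        ages = {p: 10.0 for p in kept.participant_id.unique()}
        plain = HierarchicalDDM(kept)
        adj = HierarchicalDDM(kept, ages=ages)
        theta = np.empty(plain.n_params)
        for i in range(plain.P):
            theta[5 * i : 5 * i + 5] = PARAMS.as_array()
        theta[plain.P * 5 :] = HYPERS.as_array()
        betas = np.array([0.3, -0.1, 0.2, 0.05, -0.2])
        theta_adj = np.concatenate([theta, betas])
        beta_prior = float(np.sum(adj.priors.age_beta.logpdf(betas)))
        assert adj.full_logp(theta_adj) == pytest.approx(
            plain.full_logp(theta) + beta_prior, rel=1e-9
        )

    def test_missing_ages_rejected(self, tiny_fit_data):
        with pytest.raises(ValueError, match="missing ages"):
            HierarchicalDDM(tiny_fit_data, ages={"d01": 9.0})


class TestPriorPredictive:
    def test_init_draws_respect_supports(self, tiny_fit_data):
        model = HierarchicalDDM(tiny_fit_data)
        rng = np.random.default_rng(0)
        for _ in range(50):
            theta = model.init_draw(rng)
            subj = model.subject_matrix(theta)
            assert np.all(subj[:, 0] > 0)  # a
            assert np.all((subj[:, 1] > 0) & (subj[:, 1] < 1))  # z
            assert np.all(subj[:, 2] >= 0)  # ter
            base = model.P * 5
            assert np.all(theta[base + 1 :: 3][:5] > 0)  # sigmas


class TestAgeAdjustedFits:
    """Fits exercising the two age-partialling routes (scaled-down sizes)."""

    @staticmethod
    def _study_with_age_effect(beta, delta_vmean, seed):
        """Participants whose true v.mean depends linearly on age."""
        from motionddm.synth import GeneratorConfig, StudyDesign, generate_behaviour

        rng = np.random.default_rng(seed)
        parts = []
        ages = {}
        pid_n = 0
        for group, c in (("dyslexia", 1.0), ("typical", -1.0)):
            for _ in range(6):
                pid_n += 1
                pid = f"s{pid_n:02d}"
                age = float(rng.uniform(7, 13))
                ages[pid] = age
                mu = {"a": 0.2, "z": 0.5, "ter": 0.3, "v.diff": 0.1,
                      "v.mean": 0.3 + beta * (age - 10.0) + c * delta_vmean}
                d = StudyDesign(n_per_group=1, blocks_per_task=2, tasks=("motion_coherence",))
                cfg = GeneratorConfig(seed=int(rng.integers(2**31)), mu=mu)
                tr, _ = generate_behaviour(d, cfg)
                tr = tr[tr.participant_id == "d01"].assign(participant_id=pid, group=group)
                parts.append(tr)
        trials = pd.concat(parts, ignore_index=True)
        kept, _ = filter_trials(trials)
        return kept, ages

    def test_pure_age_effect_yields_null_delta(self):
        """Data with an age slope but no group difference: the age-adjusted
        delta_v.mean posterior covers 0."""
        from motionddm.sampler import SamplerConfig, run

        kept, ages = self._study_with_age_effect(beta=0.05, delta_vmean=0.0, seed=4)
        model = HierarchicalDDM(kept, ages=ages)
        res = run(model, SamplerConfig(n_chains=10, n_iter=700, burn_in=300, seed=1,
                                       migration_window=(100, 300), init="data"))
        delta = res.get("delta_v.mean")
        lo, hi = np.percentile(delta, [2.5, 97.5])
        assert lo < 0.0 < hi
        # and the age slope itself is picked up with the right sign
        assert res.get("beta_age_v.mean").mean() > 0

    def test_two_stage_residualization_produces_delta_posterior(self):
        from motionddm.hierarchy import two_stage_age_adjust
        from motionddm.sampler import SamplerConfig, run

        kept, ages = self._study_with_age_effect(beta=0.04, delta_vmean=0.0, seed=6)
        model = HierarchicalDDM(kept)
        res = run(model, SamplerConfig(n_chains=10, n_iter=500, burn_in=200, seed=2,
                                       migration_window=(80, 250), init="data"))
        out = two_stage_age_adjust(
            res, model, ages,
            sampler_config=SamplerConfig(n_chains=8, n_iter=600, burn_in=200, seed=3,
                                         migration_window=(50, 250)),
        )
        assert set(out) == set(PARAM_NAMES)
        delta = out["v.mean"].get("delta_v.mean")
        lo, hi = np.percentile(delta, [2.5, 97.5])
        assert lo < 0.0 < hi
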