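"""EEG pipeline: epoching, RCA, FIR design, masking, deconvolution, slopes."""

import numpy as np
import pytest

from motionddm.eeg import (
    DeconvolvedERP,
    build_design,
    deconvolve,
    epoch_and_baseline,
    extract_slope,
    mask_artifacts,
    modal_lambda,
    rca_fit,
    rca_project,
    select_lambda,
)
from motionddm.io import EEGRecording
from motionddm.synth import (
    GeneratorConfig,
    StudyDesign,
    generate_behaviour,
    generate_eeg,
    plant_slopes,
    _response_kernel,
)

SFREQ = 250.0


def _events(times, etype="stimulus", difficulty="easy"):
    return [{"time_s": t, "type": etype, "difficulty": difficulty} for t in times]


class TestEpochAndBaseline:
    def _rec(self, data, stim, resp):
        ev = _events(stim) + _events(resp, "response")
        return EEGRecording(data=data, sfreq=SFREQ, events=ev)

    def test_constant_channel_baselines_to_zero(self):
        rec = self._rec(np.full((2, 3000), 7.5), [2.0, 6.0], [3.0, 7.0])
        ep = epoch_and_baseline(rec)
        assert np.allclose(ep.data, 0.0)
        assert ep.data.shape[0] == 2

    def test_per_trial_dc_offset_removed_exactly(self, rng):
        n = 6000
        data = np.zeros((1, n))
        stim, resp = [2.0, 12.0], [3.0, 13.0]
        offsets = [4.0, -2.5]
        for (s, r), off in zip(zip(stim, resp), offsets):
            data[0, int((s - 1.0) * SFREQ) : int((r + 0.5) * SFREQ)] += off
        ep = epoch_and_baseline(self._rec(data, stim, resp))
        assert np.allclose(ep.data, 0.0, atol=1e-12)

    def test_boundary_epochs_dropped_and_counted(self):
        # second response's epoch would run past the recording end
        rec = self._rec(np.zeros((1, int(4.1 * SFREQ))), [0.5, 3.6], [1.2, 4.05])
        ep = epoch_and_baseline(rec)
        assert ep.data.shape[0] == 1
        assert ep.n_dropped == 1


class TestRCA:
    def test_recovers_planted_topography(self, rng):
        """Rank-1 planted component at SNR 1: |corr(weights, topography)| > 0.95."""
        n, C, T = 100, 32, 60
        topo = rng.normal(size=C)
        topo /= np.linalg.norm(topo)
        shared = rng.normal(size=(1, 1, T))  # reliable: identical across trials
        noise = rng.normal(size=(n, C, T))
        X = topo[None, :, None] * shared + noise
        model = rca_fit(X)
        r = np.corrcoef(model.weights[:, 0], topo)[0, 1]
        assert abs(r) > 0.95
        assert np.all(np.diff(model.reliability) <= 1e-9)

    def test_pure_noise_reliability_near_zero(self, rng):
        n, C, T = 80, 16, 40
        X = rng.normal(size=(n, C, T))
        obs = rca_fit(X).reliability[0]
        null = []
        for _ in range(20):
            Xs = X.copy()
            for i in range(n):  # circular-shift each trial: breaks alignment
                Xs[i] = np.roll(Xs[i], rng.integers(T), axis=1)
            null.append(rca_fit(Xs).reliability[0])
        assert obs <= np.percentile(null, 95) + 0.05

    def test_duplicating_trials_leaves_weights_unchanged(self, rng):
        X = rng.normal(size=(30, 8, 40)) + rng.normal(size=(1, 8, 40))
        w1 = rca_fit(X).weights[:, 0]
        w2 = rca_fit(np.concatenate([X, X])).weights[:, 0]
        assert min(np.linalg.norm(w1 - w2), np.linalg.norm(w1 + w2)) < 1e-8

    def test_forward_projection_sign_convention(self, rng):
        X = rng.normal(size=(40, 6, 30))
        model = rca_fit(X)
        for j in range(model.forward.shape[1]):
            assert model.forward[np.argmax(np.abs(model.forward[:, j])), j] > 0


class TestDesignMatrix:
    def test_paper_scale_dimensions(self):
        """2 event types x 2 difficulties x 500 lags at 250 Hz over [-1, 1) s."""
        ev = _events([5.0]) + _events([6.0], "response") + _events([8.0], difficulty="hard")
        d = build_design(ev, SFREQ, n_samples=3000)
        assert d.n_lags == 500
        assert d.X.shape[1] == 2000
        assert len(d.conditions) == 4

    def test_single_event_is_shifted_identity(self):
        d = build_design(_events([4.0]), SFREQ, n_samples=2000, window=(-0.4, 0.4))
        sub = d.X[:, :d.n_lags].toarray()
        rows, cols = np.nonzero(sub)
        assert len(rows) == d.n_lags
        np.testing.assert_array_equal(np.diff(rows), np.ones(d.n_lags - 1))
        np.testing.assert_array_equal(np.diff(cols), np.ones(d.n_lags - 1))

    def test_two_close_events_overlap_rows_have_two_nonzeros(self):
        d = build_design(_events([4.0, 4.1]), SFREQ, n_samples=2500, window=(-0.4, 0.4))
        row_counts = np.asarray((d.X > 0).sum(axis=1)).ravel()
        t = np.arange(2500) / SFREQ
        overlap = (t >= 4.1 - 0.4) & (t < 4.0 + 0.4)
        assert np.all(row_counts[overlap] == 2)
        assert row_counts.max() == 2

    def test_empty_event_list_rejected(self):
        with pytest.raises(ValueError):
            build_design([], SFREQ, n_samples=100)


class TestArtifactMask:
    def test_clean_signal_nothing_excluded(self):
        mask, frac = mask_artifacts(np.zeros(10_000), SFREQ)
        assert frac == 0.0

    def test_single_spike_excludes_full_surrounding_windows(self):
        x = np.zeros(10_000)
        x[5000] = 300.0
        mask, frac = mask_artifacts(x, SFREQ)
        assert mask[5000]
        assert mask.sum() >= int(2.0 * SFREQ)  # at least one full segment
        assert not mask[0] and not mask[-1]

    def test_planted_contamination_fraction_recovered(self, rng):
        n = int(200 * SFREQ)
        x = rng.normal(0, 10, n)
        # plant spikes inside a known 5% stretch (10 s of 200 s)
        x[int(20 * SFREQ) : int(30 * SFREQ) : int(SFREQ)] = 400.0
        mask, frac = mask_artifacts(x, SFREQ)
        # spikes every 1 s from 20..29 s: exclusion spans ~ [18.1, 31.9] s
        expected = (29.0 - 20.0 + 2 * 1.9 + 0.1) / 200.0
        assert frac == pytest.approx(expected, abs=2.1 / 200.0)  # one window's slack


def _toy_kernel_system(rng, gap=2.0, n_events=12, klen=100, noise=0.0):
    kern = np.hanning(klen) * 3.0
    times = 3.0 + gap * np.arange(n_events)
    n = int((times[-1] + 3.0) * SFREQ)
    y = np.zeros(n)
    for t in times:
        s = int(t * SFREQ)
        y[s : s + klen] += kern
    if noise:
        y = y + rng.normal(0, noise, n)
    ev = _events(times)
    design = build_design(
        ev, SFREQ, n, window=(0.0, klen / SFREQ),
        event_types=("stimulus",), difficulties=("easy",),
    )
    return design, y, kern


class TestDeconvolve:
    def test_nonoverlapping_kernels_recovered_exactly(self, rng):
        design, y, kern = _toy_kernel_system(rng, gap=2.0)
        erp = deconvolve(design, y, lam=0.0)
        np.testing.assert_allclose(erp.betas[("stimulus", "easy")], kern, atol=1e-9)

    def test_equals_trial_average_when_no_overlap(self, rng):
        design, y, kern = _toy_kernel_system(rng, gap=2.0)
        erp = deconvolve(design, y, lam=0.0)
        klen = len(kern)
        avg = np.mean(
            [y[int(3.0 * SFREQ) + int(2.0 * SFREQ) * i :][:klen] for i in range(12)], axis=0
        )
        np.testing.assert_allclose(erp.betas[("stimulus", "easy")], avg, atol=1e-6)

    def test_overlapping_kernels_recovered_where_identifiable(self, rng):
        design, y, kern = _toy_kernel_system(rng, gap=0.2, n_events=40, klen=100)
        erp = deconvolve(design, y, lam=0.0)
        got = erp.betas[("stimulus", "easy")]
        assert np.max(np.abs(got - kern)) < 1e-6

    def test_ridge_shrinks_norm_monotonically(self, rng):
        design, y, _ = _toy_kernel_system(rng, gap=0.5, noise=1.0)
        norms = [
            np.linalg.norm(np.concatenate(list(deconvolve(design, y, lam=l).betas.values())))
            for l in (0.0, 1.0, 10.0, 100.0, 1e4)
        ]
        assert np.all(np.diff(norms) < 0)

    def test_negative_penalty_rejected(self, rng):
        design, y, _ = _toy_kernel_system(rng)
        with pytest.raises(ValueError):
            deconvolve(design, y, lam=-1.0)

    def test_masked_samples_ignored(self, rng):
        design, y, kern = _toy_kernel_system(rng, gap=2.0)
        y2 = y.copy()
        corrupt = slice(0, int(1.0 * SFREQ))
        y2[corrupt] = 1e3
        mask = np.zeros(len(y), bool)
        mask[corrupt] = True
        erp = deconvolve(design, y2, lam=0.0, mask=mask)
        np.testing.assert_allclose(erp.betas[("stimulus", "easy")], kern, atol=1e-9)


class TestSelectLambda:
    def test_modal_rule_prefers_most_frequent_then_smallest(self):
        assert modal_lambda([5.0, 10.0, 10.0]) == 10.0
        assert modal_lambda([5.0, 10.0]) == 5.0

    def test_pure_noise_prefers_max_penalty(self, rng):
        grid = np.array([0.0, 1.0, 10.0, 100.0])
        parts = []
        for _ in range(2):
            ev = _events(3.0 + 0.3 * np.arange(20))
            n = int(12 * SFREQ)
            design = build_design(ev, SFREQ, n, window=(0.0, 0.4))
            y = rng.normal(0, 5, n)
            parts.append((design, y, None))
        lam, best = select_lambda(parts, grid=grid, k=4)
        assert lam == 100.0

    def test_noiseless_identifiable_prefers_no_penalty(self, rng):
        grid = np.array([0.0, 1.0, 10.0])
        design, y, _ = _toy_kernel_system(rng, gap=2.0)
        lam, best = select_lambda([(design, y, None)], grid=grid, k=4)
        assert lam == 0.0


class TestExtractSlope:
    def _erp(self, easy, hard):
        lags = np.arange(-250, 250) / SFREQ
        return DeconvolvedERP(
            betas={("response", "easy"): easy, ("response", "hard"): hard},
            lags_s=lags, sfreq=SFREQ, lam=0.0,
        )

    def test_linear_ramp_slope_in_uv_per_s(self):
        lags = np.arange(-250, 250) / SFREQ
        ramp = np.where((lags >= -0.2) & (lags <= 0.0), (lags + 0.2) * 5.0, 0.0)
        sm = extract_slope(self._erp(ramp, np.zeros_like(ramp)))
        assert sm.slope_easy == pytest.approx(5.0, rel=1e-6)
        assert sm.slope_hard == pytest.approx(0.0, abs=1e-9)
        assert sm.eeg_mean == pytest.approx(2.5, rel=1e-6)
        assert sm.eeg_diff == pytest.approx(5.0, rel=1e-6)

    def test_noisy_ramp_recovered_within_mc_error(self, rng):
        lags = np.arange(-250, 250) / SFREQ
        sel = (lags >= -0.2) & (lags <= 0.0)
        truth = 5.0
        ests = []
        for _ in range(100):
            y = np.where(sel, (lags + 0.2) * truth, 0.0) + rng.normal(0, 0.1, len(lags))
            ests.append(extract_slope(self._erp(y, y)).slope_easy)
        se = np.std(ests, ddof=1) / 10.0
        assert abs(np.mean(ests) - truth) < 3 * se

    def test_window_not_covered_rejected(self):
        erp = DeconvolvedERP(
            betas={("response", "easy"): np.zeros(10), ("response", "hard"): np.zeros(10)},
            lags_s=np.linspace(0.1, 0.5, 10), sfreq=SFREQ, lam=0.0,
        )
        with pytest.raises(ValueError):
            extract_slope(erp)


class TestEndToEnd:
    def test_noiseless_pipeline_recovers_kernels_and_slopes(self):
        """generate_eeg -> design -> OLS deconvolution recovers the planted
        response kernel (r > 0.99) and the planted slopes (r > 0.95)."""
        d = StudyDesign(n_per_group=4, blocks_per_task=1, tasks=("motion_coherence",))
        cfg = GeneratorConfig(seed=77, noise_sd=0.0)
        trials, truth = generate_behaviour(d, cfg)
        sl = plant_slopes(truth, cfg, np.random.default_rng(3))
        got, planted = [], []
        for pid in sl.participant_id:
            sub = trials[trials.participant_id == pid]
            row = sl[sl.participant_id == pid]
            rec = generate_eeg(sub, row, cfg)
            design = build_design(rec.events, rec.sfreq, rec.n_samples)
            erp = deconvolve(design, rec.data[0], lam=0.0)
            kern, _ = _response_kernel(rec.sfreq, float(row.slope_easy.iloc[0]))
            lagsel = (erp.lags_s >= -0.4 - 1e-9) & (erp.lags_s <= 0.0 + 1e-9)
            beta = erp.betas[("response", "easy")][lagsel]
            r = np.corrcoef(beta, kern[: len(beta)])[0, 1]
            assert r > 0.99
            sm = extract_slope(erp)
            got += [sm.slope_easy, sm.slope_hard]
            planted += [float(row.slope_easy.iloc[0]), float(row.slope_hard.iloc[0])]
        assert np.corrcoef(got, planted)[0, 1] > 0.95

    def test_multichannel_rca_projection_recovers_component(self, rng):
        d = StudyDesign(n_per_group=1, blocks_per_task=1, tasks=("motion_coherence",))
        cfg = GeneratorConfig(seed=78, noise_sd=3.0, n_channels=8)
        trials, truth = generate_behaviour(d, cfg)
        sl = plant_slopes(truth, cfg, rng)
        sub = trials[trials.participant_id == "d01"]
        rec = generate_eeg(sub, sl[sl.participant_id == "d01"], cfg, rng)
        ep = epoch_and_baseline(rec)
        model = rca_fit(ep)
        topo = np.hanning(10)[1:-1]
        r = np.corrcoef(model.forward[:, 0], topo)[0, 1]
        assert abs(r) > 0.9
        wave = rca_project(rec, model)
        assert wave.shape == (rec.n_samples,)
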