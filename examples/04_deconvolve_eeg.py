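"""Deconvolve overlapping stimulus- and response-locked EEG activity.

Synthesizes one participant's continuous EEG (overlapping kernels + AR(1)
noise), builds the time-expanded FIR design (500 lags per event type x
difficulty at 250 Hz), masks artifact windows, ridge-deconvolves, and
extracts the pre-response slope over -200..0 ms. The printed slopes are in
microvolts/second and should sit near the planted values.
"""

import numpy as np

from motionddm.eeg import build_design, deconvolve, extract_slope, mask_artifacts
from motionddm.synth import GeneratorConfig, StudyDesign, generate_behaviour, generate_eeg, plant_slopes

design = StudyDesign(n_per_group=1, tasks=("motion_coherence",))
config = GeneratorConfig(seed=8, noise_sd=5.0)
trials, truth = generate_behaviour(design, config)
slopes = plant_slopes(truth, config, np.random.default_rng(1))

pid = "d01"
sub = trials[trials.participant_id == pid]
row = slopes[slopes.participant_id == pid]
rec = generate_eeg(sub, row, config, np.random.default_rng(2))
print(f"continuous EEG: {rec.n_samples} samples at {rec.sfreq:.0f} Hz, "
      f"{len(rec.events)} events")

mask, frac = mask_artifacts(rec.data[0], rec.sfreq)
print(f"artifact exclusion: {frac * 100:.2f}% of samples")

dmat = build_design(rec.events, rec.sfreq, rec.n_samples)
print(f"FIR design: {dmat.X.shape[0]} samples x {dmat.X.shape[1]} predictors "
      f"({dmat.n_lags} lags per event type x difficulty)")

erp = deconvolve(dmat, rec.data[0], lam=5.0, mask=mask)
sm = extract_slope(erp)
print(f"extracted slopes (uV/s): easy {sm.slope_easy:+.2f} "
      f"(planted {float(row.slope_easy.iloc[0]):+.2f}), "
      f"hard {sm.slope_hard:+.2f} (planted {float(row.slope_hard.iloc[0]):+.2f})")
print(f"EEG.mean {sm.eeg_mean:+.2f}, EEG.diff {sm.eeg_diff:+.2f}")
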