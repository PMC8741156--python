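"""Generate a synthetic two-group motion-discrimination study.

Builds the default study structure (2 tasks x 4 blocks x 38 trials, 2500 ms
response deadline) for 5 children per group, with response times drawn from
a Wiener diffusion process whose parameters vary across children, and prints
the structural counts plus basic behaviour. The points line reproduces the
per-block motivation score: round((1 / median RT) * n_correct * 2), floored
at 10.
"""

import numpy as np

from motionddm.synth import GeneratorConfig, StudyDesign, block_points, generate_behaviour

design = StudyDesign(n_per_group=5)
config = GeneratorConfig(seed=11)
trials, truth = generate_behaviour(design, config)

print(f"participants: {trials.participant_id.nunique()} "
      f"({design.n_per_group} per group)")
print(f"trials per task: {trials.groupby(['participant_id', 'task']).size().unique()}")
print(f"trials per block: {trials.groupby(['participant_id', 'task', 'block']).size().unique()}")

resp = trials[~trials.timeout & ~trials.catch]
acc = (resp.response == resp.direction).mean()
print(f"accuracy (non-catch, responded): {acc:.3f}")
print(f"median RT: {resp.rt_s.median():.3f} s")
print(f"timeout rate: {trials.timeout.mean() * 100:.2f}% "
      "(non-responses at the 2500 ms deadline)")

blk = resp[(resp.participant_id == "d01")
           & (resp.task == "motion_coherence") & (resp.block == 1)]
pts = block_points(blk.rt_s.median(), (blk.response == blk.direction).sum())
print(f"block points for d01, block 1: {pts} "
      "(speed x accuracy score shown to the child)")
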