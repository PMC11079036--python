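"""Sweep simulated impairment and watch the trial score respond.

Runs closed-loop trials over a grid of tremor amplitudes and pinch
reliabilities and prints the mean score per cell: scores fall as tremor
grows and as the pinch becomes less reliable, the qualitative behavior a
dexterity score must show to be a useful impairment measure.
"""

import arbbt as a

cfg = a.SessionConfig(trial_duration=30.0)  # shorter trials for a quick sweep
table = a.score_vs_impairment_curve(
    tremor_sds=[0.0, 10.0, 20.0],
    reliabilities=[1.0, 0.9, 0.8],
    cfg=cfg,
    replicates=3,
    seed=0,
)
print(table.to_string(index=False))
# mean_score is averaged over seeded replicate trials; sd_score shows
# run-to-run spread. Reading down a column (rising tremor) or across a
# row (falling reliability), the mean score declines.
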