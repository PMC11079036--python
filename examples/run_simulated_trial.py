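"""Run one simulated 60-s trial with a moderately impaired subject.

A closed-loop virtual hand reaches each spawned block, pinch-grabs it,
carries it over the divider, and releases it in the target compartment,
degraded by tremor, an unreliable pinch, and a slowed reach. Prints the
trial score (blocks transferred), the event tallies, and per-transfer
kinematics.
"""

import arbbt as a

cfg = a.SessionConfig()  # 60-s trial, 720p/60fps stream, 150 blocks
subject = a.impaired_subject()  # tremor 8 px, pinch reliability 0.92, 450 px/s

sim = a.simulate_trial(subject, cfg, seed=1)
result = sim.result

print(f"score: {result.score} blocks in {result.duration:.0f} s")
print(
    f"grabs: {result.counts['grabs']}, drops: {result.counts['drops']}, "
    f"divider collisions: {result.counts['divider_collisions']}"
)
kin = result.kinematics_frame()
print(
    f"mean transfer duration: {kin['transfer_duration'].mean():.2f} s, "
    f"mean path length: {kin['path_length'].mean():.0f} px, "
    f"mean peak speed: {kin['peak_speed'].mean():.0f} px/s"
)
# The score is the dexterity measure; the kinematics are the extra
# signal a camera-based test adds over the physical one: how long each
# transfer took, how far the hand travelled, and how fast it moved.
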