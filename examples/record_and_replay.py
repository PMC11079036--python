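"""Record a landmark stream to JSONL and replay it bit-faithfully.

Simulates a short trial, writes the emitted 21-landmark stream to disk,
reads it back, and reruns the engine on the recorded stream: the replay
reproduces the original event log byte for byte. This is the audit path
for clinical use — any session can be re-scored offline from its stream.
"""

import tempfile
from pathlib import Path

import arbbt as a

cfg = a.SessionConfig(trial_duration=15.0)
sim = a.simulate_trial(a.impaired_subject(), cfg, seed=4)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "stream.jsonl"
    a.write_jsonl(sim.frames, path)
    print(f"wrote {len(sim.frames)} frames ({path.stat().st_size} bytes)")

    replayed = a.run_trial(a.read_jsonl(path), cfg, seed=4)

identical = replayed.events_jsonl_bytes() == sim.result.events_jsonl_bytes()
print(f"replayed score: {replayed.score} (original {sim.result.score})")
print(f"event logs byte-identical: {identical}")
# Determinism is the contract: same stream + same seed => same events,
# same score, same kinematics, on any machine.
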