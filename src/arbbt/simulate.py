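"""Synthetic hand-motion simulation.

Generates landmark-frame streams of a parameterized virtual subject
performing the test, so every engine path is exercisable without a
camera. Two modes:

* **Closed loop** (:class:`ClosedLoopHand`, :func:`simulate_trial`): the
  virtual hand observes the arena's published state (current block
  position and lifecycle state only), reaches the block, pinches,
  carries it along an arc whose apex is set by ``carry_height_fraction``,
  and opens over the target compartment — then repeats. Impairment is
  modelled by per-frame white Gaussian positional tremor and a per-frame
  pinch-close reliability.

* **Open loop** (:class:`ScriptedPlan`, :func:`ideal_transfer_plan`):
  piecewise-linear waypoint scripts with commanded apertures, for unit
  tests needing exact frame-level control; the ideal plan performs one
  transfer every ``cycle_time`` seconds, so a trial scores exactly
  ``floor(duration / cycle_time)``.

Landmark synthesis places the 19 non-tip landmarks by a fixed synthetic
hand template rigidly translated with the carry point; only the thumb
and index tips carry behavioral meaning (the engine reads only tips).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .arena import ArenaObservation, BlockState
from .landmarks import (
    INDEX_TIP,
    N_LANDMARKS,
    THUMB_TIP,
    LandmarkFrame,
    StreamConfig,
)
from .session import SessionConfig, TrialResult, run_trial

# Synthetic hand template: pixel offsets of the 21 landmarks relative to
# the pinch point (thumb-tip/index-tip midpoint), right hand, palm facing
# the camera, fingers up. Tips 4 and 8 are overwritten per frame by the
# commanded aperture. z is a plausible relative depth, unused by the engine.
_HAND_TEMPLATE = np.array(
    [
        (10.0, 150.0, 0.00),   # 0 wrist
        (-35.0, 120.0, -0.01),  # 1 thumb cmc
        (-55.0, 85.0, -0.02),   # 2 thumb mcp
        (-55.0, 45.0, -0.03),   # 3 thumb ip
        (-50.0, 0.0, -0.04),    # 4 thumb tip (dynamic)
        (15.0, 85.0, -0.01),    # 5 index mcp
        (25.0, 45.0, -0.02),    # 6 index pip
        (35.0, 20.0, -0.03),    # 7 index dip
        (50.0, 0.0, -0.04),     # 8 index tip (dynamic)
        (40.0, 90.0, -0.01),    # 9 middle mcp
        (55.0, 50.0, -0.02),    # 10 middle pip
        (65.0, 25.0, -0.03),    # 11 middle dip
        (75.0, 5.0, -0.04),     # 12 middle tip
        (60.0, 100.0, -0.01),   # 13 ring mcp
        (75.0, 65.0, -0.02),    # 14 ring pip
        (85.0, 40.0, -0.03),    # 15 ring dip
        (95.0, 20.0, -0.04),    # 16 ring tip
        (80.0, 115.0, -0.01),   # 17 pinky mcp
        (95.0, 85.0, -0.02),    # 18 pinky pip
        (102.0, 65.0, -0.03),   # 19 pinky dip
        (110.0, 45.0, -0.04),   # 20 pinky tip
    ],
    dtype=float,
)
assert _HAND_TEMPLATE.shape == (N_LANDMARKS, 3)


@dataclass(frozen=True)
class SubjectModel:
    """Kinematic parameters of a simulated subject's hand.

    reach_speed: straight-line hand speed, px/s.
    tremor_sd: per-frame white Gaussian positional noise, px.
    pinch_close_reliability: probability a commanded pinch registers
        closed on a given frame.
    aperture_open / aperture_closed: commanded tip separations, px.
    reaction_lag: delay before moving toward a newly spawned block, s.
    regrip_delay: recovery time after an involuntary drop before the
        subject re-forms the pinch, s.
    carry_height_fraction: fraction of box height at which blocks are
        carried over the divider (must exceed the divider-top fraction to
        clear it).
    """

    reach_speed: float = 700.0
    tremor_sd: float = 0.0
    pinch_close_reliability: float = 1.0
    aperture_open: float = 120.0
    aperture_closed: float = 30.0
    reaction_lag: float = 0.0
    regrip_delay: float = 0.25
    carry_height_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.pinch_close_reliability <= 1.0:
            raise ValueError("pinch_close_reliability must lie in [0, 1]")
        if self.reach_speed <= 0:
            raise ValueError("reach_speed must be positive")
        if self.tremor_sd < 0:
            raise ValueError("tremor_sd must be non-negative")
        if self.aperture_closed >= self.aperture_open:
            raise ValueError("aperture_closed must be below aperture_open")

    def to_json_dict(self) -> dict:
        return {
            "reach_speed": self.reach_speed,
            "tremor_sd": self.tremor_sd,
            "pinch_close_reliability": self.pinch_close_reliability,
            "aperture_open": self.aperture_open,
            "aperture_closed": self.aperture_closed,
            "reaction_lag": self.reaction_lag,
            "regrip_delay": self.regrip_delay,
            "carry_height_fraction": self.carry_height_fraction,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SubjectModel":
        return cls(**d)


def impaired_subject(
    tremor_sd: float = 8.0,
    pinch_close_reliability: float = 0.92,
    reach_speed: float = 450.0,
    reaction_lag: float = 0.25,
) -> SubjectModel:
    """A moderately impaired subject profile (slowed reach, tremor,
    unreliable pinch), calibrated so simulated 60-s scores fall in the
    low-teens range reported for hemiplegic stroke patients on virtual
    block-transfer tests."""
    return SubjectModel(
        reach_speed=reach_speed,
        tremor_sd=tremor_sd,
        pinch_close_reliability=pinch_close_reliability,
        reaction_lag=reaction_lag,
    )


def synthesize_frame(
    t: float,
    center: Tuple[float, float],
    aperture: float,
    stream: StreamConfig,
    handedness: str = "right",
    confidence: float = 1.0,
) -> LandmarkFrame:
    """Build a schema-valid 21-landmark frame around a pinch point.

    Thumb and index tips sit ``aperture`` apart, symmetric about
    ``center``; the remaining landmarks follow the rigid synthetic hand
    template. Pixel coordinates are normalized and clipped to [0, 1].
    """
    pts = _HAND_TEMPLATE.copy()
    pts[:, 0] += center[0]
    pts[:, 1] += center[1]
    half = aperture / 2.0
    pts[THUMB_TIP, 0:2] = (center[0] - half, center[1])
    pts[INDEX_TIP, 0:2] = (center[0] + half, center[1])
    pts[:, 0] = np.clip(pts[:, 0] / stream.frame_width, 0.0, 1.0)
    pts[:, 1] = np.clip(pts[:, 1] / stream.frame_height, 0.0, 1.0)
    return LandmarkFrame(
        t=t, handedness=handedness, landmarks=pts, confidence=confidence
    )


def frame_from_tips(
    t: float,
    thumb: Tuple[float, float],
    index: Tuple[float, float],
    stream: StreamConfig,
    handedness: str = "right",
) -> LandmarkFrame:
    """Frame with exact pixel tip positions (test/fixture convenience);
    non-tip landmarks follow the template around the tip midpoint."""
    center = ((thumb[0] + index[0]) / 2.0, (thumb[1] + index[1]) / 2.0)
    pts = _HAND_TEMPLATE.copy()
    pts[:, 0] += center[0]
    pts[:, 1] += center[1]
    pts[THUMB_TIP, 0:2] = thumb
    pts[INDEX_TIP, 0:2] = index
    pts[:, 0] = np.clip(pts[:, 0] / stream.frame_width, 0.0, 1.0)
    pts[:, 1] = np.clip(pts[:, 1] / stream.frame_height, 0.0, 1.0)
    return LandmarkFrame(t=t, handedness=handedness, landmarks=pts)


# ---------------------------------------------------------------------------
# Open-loop scripted plans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlanSegment:
    """Linear motion from pos_start to pos_end over [t_start, t_end) at a
    constant commanded aperture."""

    t_start: float
    t_end: float
    pos_start: Tuple[float, float]
    pos_end: Tuple[float, float]
    aperture: float


@dataclass(frozen=True)
class ScriptedPlan:
    """Ordered piecewise-linear waypoint script with commanded apertures."""

    segments: Tuple[PlanSegment, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if b.t_start < a.t_end:
                raise ValueError("segments must be time-ordered")

    def sample(self, t: float) -> Tuple[Tuple[float, float], float]:
        """Position and aperture at time t (clamps to plan ends)."""
        segs = self.segments
        if t < segs[0].t_start:
            return segs[0].pos_start, segs[0].aperture
        for seg in segs:
            if seg.t_start <= t < seg.t_end:
                span = seg.t_end - seg.t_start
                u = 0.0 if span <= 0 else (t - seg.t_start) / span
                pos = (
                    seg.pos_start[0] + u * (seg.pos_end[0] - seg.pos_start[0]),
                    seg.pos_start[1] + u * (seg.pos_end[1] - seg.pos_start[1]),
                )
                return pos, seg.aperture
        last = segs[-1]
        return last.pos_end, last.aperture

    def to_stream(
        self,
        stream: StreamConfig,
        duration: float,
        fps: Optional[float] = None,
        handedness: str = "right",
    ) -> List[LandmarkFrame]:
        """Sample the plan at the frame rate; the final frame lands at or
        past ``duration`` so a trial of that length terminates cleanly."""
        fps = fps if fps is not None else stream.fps_nominal
        dt = 1.0 / fps
        n = int(np.ceil(duration * fps)) + 1
        frames = []
        for k in range(1, n + 1):
            t = k * dt
            pos, aperture = self.sample(t)
            frames.append(
                synthesize_frame(t, pos, aperture, stream, handedness=handedness)
            )
        return frames


def ideal_transfer_plan(
    cfg: SessionConfig,
    cycle_time: float,
    aperture_open: float = 120.0,
    aperture_closed: float = 30.0,
) -> ScriptedPlan:
    """Scripted ideal subject: one transfer every ``cycle_time`` seconds.

    Assumes ``cfg.arena.spawn_mode == "center"`` so every block spawns at
    the source-compartment centre. Each cycle: settle at the spawn point
    (open), pinch (closed), carry via an apex over the divider to the
    target-compartment centre, open to release at 85% of the cycle —
    so transfer k completes at (k - 0.15) * cycle_time and a trial of
    duration D scores exactly floor(D / cycle_time) whenever
    frac(D / cycle_time) <= 0.85.
    """
    from .arena import BoxLayout  # local import to avoid cycle at module load

    layout = BoxLayout.build(cfg.stream, cfg.arena)
    spawn_region = layout.source.shrink(cfg.arena.spawn_margin)
    p = spawn_region.center
    apex = (
        layout.divider.center[0],
        layout.box.y1 - 0.8 * layout.box.height,
    )
    q = layout.target.center
    c = cycle_time
    n_cycles = int(np.ceil(cfg.trial_duration / c)) + 1
    segments: List[PlanSegment] = []
    for k in range(n_cycles):
        t0 = k * c
        segments += [
            PlanSegment(t0, t0 + 0.20 * c, p, p, aperture_open),
            PlanSegment(t0 + 0.20 * c, t0 + 0.35 * c, p, p, aperture_closed),
            PlanSegment(t0 + 0.35 * c, t0 + 0.60 * c, p, apex, aperture_closed),
            PlanSegment(t0 + 0.60 * c, t0 + 0.85 * c, apex, q, aperture_closed),
            PlanSegment(t0 + 0.85 * c, t0 + 1.00 * c, q, q, aperture_open),
        ]
    return ScriptedPlan(segments=tuple(segments))


# ---------------------------------------------------------------------------
# Closed-loop virtual subject
# ---------------------------------------------------------------------------

_MOTOR_STREAM_KEY = 101  # sub-seed tag for the subject's motor noise


class ClosedLoopHand:
    """Closed-loop virtual subject satisfying the provider contract.

    ``run_trial`` binds it to the arena's published observation; on each
    frame the controller reads the active block's position and state,
    moves the hand toward its current goal at ``reach_speed``, commands
    the pinch aperture, applies tremor, and emits a landmark frame.
    Deterministic per seed; ``frames`` accumulates the emitted stream so
    a simulated trial can be replayed verbatim.
    """

    def __init__(
        self,
        subject: SubjectModel,
        cfg: SessionConfig,
        seed: int = 0,
        handedness: Optional[str] = None,
    ) -> None:
        self.subject = subject
        self.cfg = cfg
        self.seed = seed
        self.handedness = (
            handedness if handedness is not None else cfg.arena.assessed_side
        )
        self.rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), _MOTOR_STREAM_KEY])
        )
        self.frames: List[LandmarkFrame] = []
        self._observe: Optional[Callable[[], ArenaObservation]] = None

    def bind(self, observe: Callable[[], ArenaObservation]) -> None:
        self._observe = observe

    def __iter__(self):
        sub = self.subject
        cfg = self.cfg
        fps = cfg.stream.fps_nominal
        dt = 1.0 / fps
        n_steps = int(np.ceil(cfg.trial_duration * fps)) + 1
        pos = np.array(
            [cfg.stream.frame_width / 2.0, cfg.stream.frame_height / 2.0]
        )
        mode = "approach"
        lag_until = 0.0
        next_attempt_at = 0.0
        target_block_id: Optional[int] = None
        was_carrying = False
        close_radius = cfg.arena.block_half_size * 0.5

        for k in range(1, n_steps + 1):
            t = k * dt
            obs = self._observe() if self._observe is not None else None
            goal = tuple(pos)
            command_closed = False
            if obs is not None and obs.active_state is BlockState.RESTING:
                if obs.active_block_id != target_block_id:
                    target_block_id = obs.active_block_id
                    lag_until = t + sub.reaction_lag
                elif was_carrying:
                    # involuntary drop of the carried block: recover grip
                    lag_until = t + max(sub.reaction_lag, sub.regrip_delay)
                mode = "approach"
                if t >= lag_until:
                    goal = obs.active_center
                    dist = float(np.hypot(pos[0] - goal[0], pos[1] - goal[1]))
                    # discrete grasp attempts: close for one frame, and on
                    # a miss re-aim for regrip_delay before trying again
                    if dist <= close_radius and t >= next_attempt_at:
                        command_closed = True
                        next_attempt_at = t + max(sub.regrip_delay, dt)
            elif obs is not None and obs.active_state is BlockState.GRABBED:
                layout = obs.layout
                apex = (
                    layout.divider.center[0],
                    layout.box.y1 - sub.carry_height_fraction * layout.box.height,
                )
                drop = layout.target.center
                if mode not in ("carry_lift", "carry_apex", "carry_drop"):
                    mode = "carry_lift"  # ascend first so the traverse clears the divider
                if mode == "carry_lift":
                    goal = (pos[0], apex[1])
                    if abs(pos[1] - apex[1]) < 1e-6:
                        mode = "carry_apex"
                if mode == "carry_apex":
                    goal = apex
                    if np.hypot(pos[0] - apex[0], pos[1] - apex[1]) < 1e-6:
                        mode = "carry_drop"
                if mode == "carry_drop":
                    goal = drop
                at_drop = np.hypot(pos[0] - drop[0], pos[1] - drop[1]) < 1e-6
                command_closed = not at_drop  # open over the drop point
            # move toward goal, snapping when within one step
            delta = np.asarray(goal, dtype=float) - pos
            dist = float(np.hypot(delta[0], delta[1]))
            step_len = sub.reach_speed * dt
            if dist <= step_len or dist == 0.0:
                pos = np.asarray(goal, dtype=float).copy()
            else:
                pos = pos + delta * (step_len / dist)
            # commanded aperture, degraded by pinch reliability
            if command_closed:
                registers = (
                    sub.pinch_close_reliability >= 1.0
                    or self.rng.random() < sub.pinch_close_reliability
                )
                aperture = sub.aperture_closed if registers else sub.aperture_open
            else:
                aperture = sub.aperture_open
            noisy = pos
            if sub.tremor_sd > 0:
                noisy = pos + self.rng.normal(0.0, sub.tremor_sd, size=2)
            frame = synthesize_frame(
                t,
                (float(noisy[0]), float(noisy[1])),
                aperture,
                cfg.stream,
                handedness=self.handedness,
            )
            was_carrying = (
                obs is not None and obs.active_state is BlockState.GRABBED
            )
            self.frames.append(frame)
            yield frame


@dataclass(frozen=True)
class SimulatedTrial:
    """A closed-loop simulated trial: its result plus the emitted stream
    (replayable verbatim through ``run_trial`` with the same seed)."""

    result: TrialResult
    frames: Tuple[LandmarkFrame, ...]


def simulate_trial(
    subject: SubjectModel, cfg: SessionConfig, seed: int = 0
) -> SimulatedTrial:
    """Run one closed-loop simulated trial; deterministic per seed."""
    provider = ClosedLoopHand(subject, cfg, seed=seed)
    result = run_trial(provider, cfg, seed=seed)
    return SimulatedTrial(result=result, frames=tuple(provider.frames))


def simulate_trial_stream(
    subject: SubjectModel, cfg: SessionConfig, seed: int = 0
) -> List[LandmarkFrame]:
    """The landmark stream of a closed-loop simulated trial."""
    return list(simulate_trial(subject, cfg, seed=seed).frames)


def score_vs_impairment_curve(
    tremor_sds: Sequence[float],
    reliabilities: Sequence[float],
    cfg: SessionConfig,
    replicates: int = 3,
    seed: int = 0,
    base_subject: Optional[SubjectModel] = None,
) -> pd.DataFrame:
    """Mean +/- SD trial score over a (tremor, reliability) grid.

    Expected behavior — mean score non-increasing in tremor and
    non-decreasing in reliability — is a property of the model, checked
    in the test suite on coarse grids.
    """
    base = base_subject if base_subject is not None else SubjectModel()
    rows = []
    for i, tremor in enumerate(tremor_sds):
        for j, rel in enumerate(reliabilities):
            subject = replace(
                base, tremor_sd=tremor, pinch_close_reliability=rel
            )
            scores = []
            for r in range(replicates):
                rep_seed = int(
                    np.random.SeedSequence([int(seed), i, j, r]).generate_state(1)[0]
                    % (2**31)
                )
                scores.append(simulate_trial(subject, cfg, seed=rep_seed).result.score)
            rows.append(
                {
                    "tremor_sd": tremor,
                    "pinch_close_reliability": rel,
                    "mean_score": float(np.mean(scores)),
                    "sd_score": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
                    "replicates": replicates,
                }
            )
    return pd.DataFrame(rows)
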