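"""Timed trials and the clinical protocol.

A trial folds :func:`step` over a time-ordered landmark stream for 60
seconds (configurable): per frame the pinch state is updated with
hysteresis, then the arena rules run (grab, carry + divider check, or
release), then a fresh block is spawned if none is active, and the clock
advances to the frame timestamp. Frames with no detected hand freeze the
arena while the clock keeps running, as in a real timed test when the
hand leaves the camera view.

The protocol runs five familiarization trials followed by one assessment
trial; only the assessment score is the reported AR-BBT score. Per-trial
seeds are derived deterministically from the session seed so spawn
sequences differ across trials but reproduce across runs.

Kinematics are extracted per scored transfer from the carry trajectory:
fingertip-midpoint path length, peak speed, transfer duration, and mean
pinch aperture.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .arena import (
    Arena,
    ArenaConfig,
    ArenaEvent,
    BlockState,
    BoxLayout,
    EventKind,
)
from .landmarks import (
    INDEX_TIP,
    THUMB_TIP,
    FrameLike,
    HandAbsent,
    LandmarkFrame,
    PinchConfig,
    PrimaryHandTracker,
    StreamConfig,
    euclidean_distance,
    pinch_closed,
    to_pixels,
)


@dataclass(frozen=True)
class SessionConfig:
    """Full configuration of one session: 60-s trials, five
    familiarization trials, stream/arena/pinch settings."""

    trial_duration: float = 60.0
    familiarization_trials: int = 5
    session_name: str = "AR-BBT"
    stream: StreamConfig = field(default_factory=StreamConfig)
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    pinch: Optional[PinchConfig] = None

    def __post_init__(self) -> None:
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.familiarization_trials < 0:
            raise ValueError("familiarization_trials must be >= 0")
        if self.pinch is None:
            object.__setattr__(self, "pinch", PinchConfig.for_stream(self.stream))

    def to_json_dict(self) -> dict:
        return {
            "trial_duration": self.trial_duration,
            "familiarization_trials": self.familiarization_trials,
            "session_name": self.session_name,
            "stream": self.stream.to_json_dict(),
            "arena": self.arena.to_json_dict(),
            "pinch": self.pinch.to_json_dict(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SessionConfig":
        return cls(
            trial_duration=d["trial_duration"],
            familiarization_trials=d["familiarization_trials"],
            session_name=d["session_name"],
            stream=StreamConfig.from_json_dict(d["stream"]),
            arena=ArenaConfig.from_json_dict(d["arena"]),
            pinch=PinchConfig.from_json_dict(d["pinch"]),
        )


@dataclass
class CarrySample:
    """One frame of a carried block's trajectory."""

    t: float
    x: float
    y: float
    aperture: float
    block_id: int


@dataclass
class TrialState:
    """The evolving session state, advanced frame by frame by :func:`step`."""

    arena: Arena
    tracker: PrimaryHandTracker = field(default_factory=PrimaryHandTracker)
    elapsed: float = 0.0
    last_t: float = -math.inf
    pinch_is_closed: bool = False
    finished: bool = False
    carry_samples: List[CarrySample] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    @property
    def score(self) -> int:
        return self.arena.score

    def hud(self, cfg: SessionConfig) -> dict:
        """The on-screen HUD as pure state: session name, clock, score,
        divider visibility."""
        remaining = max(cfg.trial_duration - self.elapsed, 0.0)
        return {
            "session_name": cfg.session_name,
            "clock": f"{remaining:05.1f}",
            "score": self.arena.score,
            "divider_visible": True,
        }


@dataclass(frozen=True)
class TransferKinematics:
    """Per-transfer kinematics of one scored block."""

    block_id: int
    start_time: float
    end_time: float
    transfer_duration: float
    path_length: float
    peak_speed: float
    mean_pinch_aperture: float

    def to_json_dict(self) -> dict:
        return {
            "block_id": self.block_id,
            "start_time": self.start_time,
            "end_time": self.end_time,
            "transfer_duration": self.transfer_duration,
            "path_length": self.path_length,
            "peak_speed": self.peak_speed,
            "mean_pinch_aperture": self.mean_pinch_aperture,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TransferKinematics":
        return cls(**d)


@dataclass(frozen=True)
class TrialResult:
    """Final report of one trial; reconciles with its event log."""

    score: int
    duration: float
    transfers: Tuple[TransferKinematics, ...]
    counts: dict
    events: Tuple[ArenaEvent, ...]
    config: dict
    seed: Optional[int]
    warnings: Tuple[str, ...] = ()

    def to_json_dict(self) -> dict:
        return {
            "score": self.score,
            "duration": self.duration,
            "transfers": [t.to_json_dict() for t in self.transfers],
            "counts": dict(self.counts),
            "events": [e.to_json_dict() for e in self.events],
            "config": self.config,
            "seed": self.seed,
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TrialResult":
        return cls(
            score=d["score"],
            duration=d["duration"],
            transfers=tuple(
                TransferKinematics.from_json_dict(t) for t in d["transfers"]
            ),
            counts=dict(d["counts"]),
            events=tuple(ArenaEvent.from_json_dict(e) for e in d["events"]),
            config=d["config"],
            seed=d["seed"],
            warnings=tuple(d["warnings"]),
        )

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "TrialResult":
        return cls.from_json_dict(json.loads(Path(path).read_text()))

    def events_jsonl_bytes(self) -> bytes:
        lines = [
            json.dumps(e.to_json_dict(), separators=(",", ":")) for e in self.events
        ]
        return ("\n".join(lines) + "\n").encode() if lines else b""

    def kinematics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.to_json_dict() for t in self.transfers])

    def kinematics_csv(self, path: Union[str, Path]) -> None:
        self.kinematics_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ProtocolResult:
    familiarization: Tuple[TrialResult, ...]
    assessment: TrialResult

    @property
    def reported_score(self) -> int:
        """The AR-BBT score: blocks transferred in the assessment trial."""
        return self.assessment.score


def _normalize_item(
    item: Union[FrameLike, Sequence[LandmarkFrame]],
) -> Tuple[float, List[LandmarkFrame]]:
    """Accept a single frame, a hand-absent marker, or a same-timestamp
    multi-hand candidate list; return (t, candidates)."""
    if isinstance(item, HandAbsent):
        return item.t, []
    if isinstance(item, LandmarkFrame):
        return item.t, [item]
    candidates = list(item)
    if not candidates:
        raise ValueError("empty candidate list has no timestamp; use HandAbsent")
    return candidates[0].t, candidates


def step(
    state: TrialState,
    item: Union[FrameLike, Sequence[LandmarkFrame]],
    cfg: SessionConfig,
) -> TrialState:
    """Advance the trial by one frame.

    Transition order: hand selection -> pinch hysteresis update -> arena
    rules (grab / carry+collision / release) -> spawn if needed -> clock
    advance. Raises on out-of-order timestamps; a frame at or past the
    trial duration marks the trial finished without being applied.
    """
    if state.finished:
        raise RuntimeError("trial already finished")
    t, candidates = _normalize_item(item)
    if not t > state.last_t:
        raise ValueError(
            f"out-of-order frame: t={t} after t={state.last_t}"
        )
    state.last_t = t
    if t >= cfg.trial_duration:
        state.elapsed = cfg.trial_duration
        state.finished = True
        return state
    state.elapsed = t

    frame = state.tracker.select(candidates)
    if frame is None:
        return state  # hand absent: arena frozen, clock advanced

    arena = state.arena
    if arena.active is None:
        arena.spawn_block(t)

    pts = to_pixels(frame, cfg.stream)
    thumb = (float(pts[THUMB_TIP, 0]), float(pts[THUMB_TIP, 1]))
    index = (float(pts[INDEX_TIP, 0]), float(pts[INDEX_TIP, 1]))
    aperture = euclidean_distance(thumb, index)
    closed = pinch_closed(frame, cfg.stream, cfg.pinch, state.pinch_is_closed)

    block = arena.active
    if block is not None:
        if block.state is BlockState.GRABBED:
            if closed:
                arena.carry(t, thumb, index)
                if block.state is BlockState.GRABBED:
                    state.carry_samples.append(
                        CarrySample(t, block.center[0], block.center[1], aperture, block.id)
                    )
            else:
                arena.try_release(t, thumb, index)
        elif block.state is BlockState.RESTING and closed:
            if arena.try_grab(t, thumb, index, closed):
                state.carry_samples.append(
                    CarrySample(t, block.center[0], block.center[1], aperture, block.id)
                )

    if arena.active is None:
        arena.spawn_block(t)

    state.pinch_is_closed = closed
    return state


def extract_kinematics(
    events: Sequence[ArenaEvent], carry_samples: Sequence[CarrySample]
) -> List[TransferKinematics]:
    """One kinematics record per scored transfer.

    A transfer spans from the last GRAB of a block to its SCORE. Path
    length sums successive carry-point displacements; peak speed is the
    largest per-frame displacement over its time step; aperture is
    averaged over the carried span. Unmatched GRABs (block never scored)
    contribute no record.
    """
    transfers: List[TransferKinematics] = []
    for i, ev in enumerate(events):
        if ev.kind is not EventKind.SCORE:
            continue
        grab_t = None
        for prev in reversed(events[:i]):
            if prev.kind is EventKind.GRAB and prev.block_id == ev.block_id:
                grab_t = prev.time
                break
        if grab_t is None:
            continue  # malformed log; skip rather than guess
        span = [
            s
            for s in carry_samples
            if s.block_id == ev.block_id and grab_t <= s.t <= ev.time
        ]
        path = 0.0
        peak = 0.0
        for a, b in zip(span, span[1:]):
            d = math.hypot(b.x - a.x, b.y - a.y)
            path += d
            dt = b.t - a.t
            if dt > 0:
                peak = max(peak, d / dt)
        mean_ap = float(np.mean([s.aperture for s in span])) if span else 0.0
        transfers.append(
            TransferKinematics(
                block_id=ev.block_id,
                start_time=grab_t,
                end_time=ev.time,
                transfer_duration=ev.time - grab_t,
                path_length=path,
                peak_speed=peak,
                mean_pinch_aperture=mean_ap,
            )
        )
    return transfers


def new_trial_state(cfg: SessionConfig, seed: Optional[int] = None) -> TrialState:
    layout = BoxLayout.build(cfg.stream, cfg.arena)
    arena = Arena(layout, cfg.arena, seed=seed)
    return TrialState(arena=arena)


def run_trial(
    provider: Iterable,
    cfg: SessionConfig,
    seed: Optional[int] = None,
) -> TrialResult:
    """Run one timed trial over a landmark stream.

    ``provider`` is any iterable of frames; a closed-loop provider (one
    exposing ``bind``) is handed a callable returning the current arena
    observation before iteration starts. Blocks still grabbed at cutoff
    are counted but never scored.
    """
    state = new_trial_state(cfg, seed=seed)
    bind = getattr(provider, "bind", None)
    if callable(bind):
        bind(state.arena.observation)
    n_frames = 0
    for item in provider:
        step(state, item, cfg)
        n_frames += 1
        if state.finished:
            break
    warnings = list(state.warnings)
    if n_frames == 0:
        warnings.append("empty_stream")
    elif not state.finished:
        warnings.append("stream_ended_early")
    arena = state.arena
    unfinished = (
        1
        if arena.active is not None and arena.active.state is BlockState.GRABBED
        else 0
    )
    counts = {
        "grabs": arena.count_events(EventKind.GRAB),
        "drops": arena.count_events(EventKind.DROP),
        "divider_collisions": arena.count_events(EventKind.DIVIDER_COLLISION),
        "clamps": arena.count_events(EventKind.CLAMP),
        "spawns": arena.count_events(EventKind.SPAWN),
        "unfinished_grab": unfinished,
    }
    duration = cfg.trial_duration if state.finished else state.elapsed
    transfers = extract_kinematics(arena.events, state.carry_samples)
    return TrialResult(
        score=arena.score,
        duration=duration,
        transfers=tuple(transfers),
        counts=counts,
        events=tuple(arena.events),
        config=cfg.to_json_dict(),
        seed=seed,
        warnings=tuple(warnings),
    )


def derive_trial_seed(session_seed: int, trial_index: int) -> int:
    """Deterministic per-trial seed from (session seed, trial index)."""
    ss = np.random.SeedSequence([int(session_seed), int(trial_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_protocol(
    provider_factory: Callable[[int, int], Iterable],
    cfg: SessionConfig,
    seed: int = 0,
) -> ProtocolResult:
    """Run the clinical protocol: familiarization trials then one
    assessment trial whose score is the reported AR-BBT score.

    ``provider_factory(trial_index, trial_seed)`` must return a fresh
    stream for each trial. Trial 0..k-1 are familiarization; trial k is
    the assessment.
    """
    fam: List[TrialResult] = []
    for i in range(cfg.familiarization_trials):
        trial_seed = derive_trial_seed(seed, i)
        fam.append(run_trial(provider_factory(i, trial_seed), cfg, seed=trial_seed))
    assess_index = cfg.familiarization_trials
    assess_seed = derive_trial_seed(seed, assess_index)
    assessment = run_trial(
        provider_factory(assess_index, assess_seed), cfg, seed=assess_seed
    )
    return ProtocolResult(familiarization=tuple(fam), assessment=assessment)
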