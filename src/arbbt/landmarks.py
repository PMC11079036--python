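"""Hand-landmark streams: data model, pinch geometry, and preprocessing.

The engine consumes time-ordered 21-point hand observations following the
standard hand-landmark topology (wrist = 0, thumb tip = 4, index fingertip
= 8), with x, y in normalized image coordinates and z a relative depth.
Any source that yields :class:`LandmarkFrame` (or :class:`HandAbsent`)
values in strictly increasing time order satisfies the provider contract:
a recorded JSONL file, the closed-loop motion simulator, or a live
camera + tracking adapter are interchangeable.

Coordinate convention, used throughout the package: pixel origin at the
top-left corner, x rightward, y downward; rectangles are half-open
``[x0, x1) x [y0, y1)`` for containment and closed for clamping/overlap.
Streams are assumed to arrive in selfie view (already mirrored);
:func:`flip_horizontal` and :func:`mirror_consistency` are the
preprocessing/diagnostic pair for sources that are not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

N_LANDMARKS = 21
WRIST = 0
THUMB_TIP = 4
INDEX_TIP = 8

HANDEDNESS_LABELS = ("left", "right")


@dataclass(frozen=True)
class StreamConfig:
    """Geometry and timing of the incoming landmark stream.

    Defaults target the recommended capture setup: 720p (1280x720) at a
    nominal 60 frames per second. An 854x480 fallback is available via
    :meth:`sd480`. ``mirror=True`` records that the stream is selfie-view.
    """

    frame_width: int = 1280
    frame_height: int = 720
    fps_nominal: float = 60.0
    mirror: bool = True

    def __post_init__(self) -> None:
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.fps_nominal <= 0:
            raise ValueError("fps_nominal must be positive")

    @classmethod
    def sd480(cls) -> "StreamConfig":
        """The 854x480 fallback resolution."""
        return cls(frame_width=854, frame_height=480)

    def to_json_dict(self) -> dict:
        return {
            "frame_width": self.frame_width,
            "frame_height": self.frame_height,
            "fps_nominal": self.fps_nominal,
            "mirror": self.mirror,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "StreamConfig":
        return cls(**d)


@dataclass(frozen=True)
class PinchConfig:
    """Pinch-gesture thresholds in pixels, with hysteresis.

    A pinch *closes* when the thumb-tip/index-tip distance falls strictly
    below ``grab_threshold`` and *opens* again only when the distance
    reaches ``release_threshold``. The defaults (64 px grab, 80 px release
    at a 1280-wide frame) are calibrated for a hand roughly 50 cm from the
    camera; use :meth:`for_stream` to scale them with resolution.
    """

    grab_threshold: float = 64.0
    release_threshold: float = 80.0

    def __post_init__(self) -> None:
        if not self.grab_threshold > 0:
            raise ValueError("grab_threshold must be positive")
        if self.release_threshold < self.grab_threshold:
            raise ValueError("release_threshold must be >= grab_threshold")

    @classmethod
    def for_stream(cls, stream: StreamConfig) -> "PinchConfig":
        """Resolution-proportional thresholds: grab = 5% of frame width."""
        grab = 0.05 * stream.frame_width
        return cls(grab_threshold=grab, release_threshold=1.25 * grab)

    def to_json_dict(self) -> dict:
        return {
            "grab_threshold": self.grab_threshold,
            "release_threshold": self.release_threshold,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PinchConfig":
        return cls(**d)


@dataclass(frozen=True)
class LandmarkFrame:
    """One timestamped 21-point hand observation.

    ``landmarks`` is a read-only float array of shape (21, 3): x, y in
    normalized image coordinates [0, 1] and z a dimensionless relative
    depth (smaller = closer to the camera).
    """

    t: float
    handedness: str
    landmarks: np.ndarray
    confidence: float = 1.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.landmarks, dtype=float)
        if pts.shape != (N_LANDMARKS, 3):
            raise ValueError(
                f"landmarks must have shape ({N_LANDMARKS}, 3), got {pts.shape}"
            )
        if np.any(pts[:, :2] < 0.0) or np.any(pts[:, :2] > 1.0):
            raise ValueError("landmark x, y must lie in [0, 1]")
        if self.handedness not in HANDEDNESS_LABELS:
            raise ValueError(f"handedness must be one of {HANDEDNESS_LABELS}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        if self.t < 0:
            raise ValueError("timestamp must be non-negative")
        pts.setflags(write=False)
        object.__setattr__(self, "landmarks", pts)


@dataclass(frozen=True)
class HandAbsent:
    """Marker for a frame in which no hand was detected.

    The session treats such frames as hand-absent: the arena state is
    frozen while the trial clock advances to ``t``.
    """

    t: float


FrameLike = Union[LandmarkFrame, HandAbsent]


def to_pixels(frame: LandmarkFrame, cfg: StreamConfig) -> np.ndarray:
    """Normalized landmarks -> pixel coordinates, shape (21, 2).

    Preserves landmark order; output lies in [0, width] x [0, height].
    """
    pts = frame.landmarks[:, :2] * np.array(
        [cfg.frame_width, cfg.frame_height], dtype=float
    )
    return pts


def euclidean_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Plane Euclidean distance between two pixel points."""
    return float(np.hypot(p[0] - q[0], p[1] - q[1]))


def pinch_aperture(frame: LandmarkFrame, cfg: StreamConfig) -> float:
    """Thumb-tip to index-tip distance in pixels."""
    pts = to_pixels(frame, cfg)
    return euclidean_distance(pts[THUMB_TIP], pts[INDEX_TIP])


def pinch_closed(
    frame: LandmarkFrame,
    cfg: StreamConfig,
    pinch: PinchConfig,
    currently_closed: bool,
) -> bool:
    """Hysteretic pinch state update.

    When open, the pinch closes iff the aperture is strictly below the
    grab threshold; when closed, it opens only once the aperture reaches
    the release threshold. The dead band in between prevents
    frame-to-frame chatter from tracking jitter.
    """
    d = pinch_aperture(frame, cfg)
    if currently_closed:
        return d < pinch.release_threshold
    return d < pinch.grab_threshold


class PrimaryHandTracker:
    """Sticky single-hand selection.

    The first hand detected is tracked (by handedness label) until it is
    lost; only then does a new first detection take over. An empty
    candidate list signals hand absence and resets tracking.
    """

    def __init__(self) -> None:
        self._label: Optional[str] = None

    @property
    def tracked_label(self) -> Optional[str]:
        return self._label

    def select(
        self, candidates: Sequence[LandmarkFrame]
    ) -> Optional[LandmarkFrame]:
        if not candidates:
            self._label = None
            return None
        if self._label is not None:
            for cand in candidates:
                if cand.handedness == self._label:
                    return cand
        first = candidates[0]
        self._label = first.handedness
        return first


def flip_horizontal(image: np.ndarray) -> np.ndarray:
    """Mirror a pixel grid about its vertical axis (column j -> w-1-j).

    An involution: applying it twice restores the input. Works on (h, w)
    and (h, w, channels) arrays alike.
    """
    image = np.asarray(image)
    if image.ndim < 2:
        raise ValueError("expected a 2-D pixel grid")
    return image[:, ::-1].copy()


def mirror_consistency(
    original: np.ndarray, flipped: np.ndarray, max_shift: int = 0
) -> float:
    """Diagnostic score for a claimed mirrored pair of images.

    Un-flips ``flipped`` and scans horizontal shifts in
    ``[-max_shift, max_shift]``, returning the minimum mean absolute
    pixel difference over the overlapping columns. Zero for an exactly
    mirrored pair (possibly offset by up to ``max_shift`` columns);
    positive otherwise.
    """
    a = np.asarray(original, dtype=float)
    b = np.asarray(flipped, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    candidate = flip_horizontal(b)
    w = a.shape[1]
    if max_shift >= w:
        raise ValueError("max_shift must be smaller than the image width")
    best = np.inf
    for s in range(-max_shift, max_shift + 1):
        a_sl = a[:, max(s, 0) : w + min(s, 0)]
        c_sl = candidate[:, max(-s, 0) : w + min(-s, 0)]
        best = min(best, float(np.mean(np.abs(a_sl - c_sl))))
    return best


# ---------------------------------------------------------------------------
# JSONL stream format: one frame per line with keys t, hand, conf, pts
# (21 [x, y, z] triples, normalized). A null pts marks a hand-absent frame.
# ---------------------------------------------------------------------------


def frame_to_json_dict(frame: FrameLike) -> dict:
    if isinstance(frame, HandAbsent):
        return {"t": frame.t, "hand": None, "conf": None, "pts": None}
    return {
        "t": frame.t,
        "hand": frame.handedness,
        "conf": frame.confidence,
        "pts": frame.landmarks.tolist(),
    }


def frame_from_json_dict(d: dict) -> FrameLike:
    if d.get("pts") is None:
        return HandAbsent(t=float(d["t"]))
    return LandmarkFrame(
        t=float(d["t"]),
        handedness=d["hand"],
        landmarks=np.asarray(d["pts"], dtype=float),
        confidence=float(d["conf"]),
    )


def frames_to_jsonl_bytes(frames: Iterable[FrameLike]) -> bytes:
    """Serialize a stream to JSONL. Float repr round-trips exactly, so
    write -> read -> write is bit-faithful."""
    lines = [
        json.dumps(frame_to_json_dict(f), separators=(",", ":"))
        for f in frames
    ]
    return ("\n".join(lines) + "\n").encode() if lines else b""


def write_jsonl(frames: Iterable[FrameLike], path: Union[str, Path]) -> None:
    Path(path).write_bytes(frames_to_jsonl_bytes(frames))


def read_jsonl(path: Union[str, Path]) -> list:
    """Read and validate a JSONL landmark stream (timestamps must be
    strictly increasing)."""
    frames: list = []
    last_t = -np.inf
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            frame = frame_from_json_dict(json.loads(line))
            if frame.t <= last_t:
                raise ValueError(
                    f"line {lineno}: timestamp {frame.t} not strictly "
                    f"increasing (previous {last_t})"
                )
            last_t = frame.t
            frames.append(frame)
    return frames


def iter_jsonl(path: Union[str, Path]) -> Iterator[FrameLike]:
    """Lazily iterate a JSONL stream (same validation as :func:`read_jsonl`)."""
    yield from read_jsonl(path)
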