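"""Optional live camera adapter.

Wraps a webcam plus a hand-tracking backend behind the provider
contract, so a live session is interchangeable with a recorded JSONL
stream or the simulator. Requires ``opencv-python`` and ``mediapipe``,
which are deliberately not dependencies of this package; the engine and
test surface never import this module.
"""

from __future__ import annotations

from typing import Iterator

from .landmarks import FrameLike, StreamConfig


def live_provider(cfg: StreamConfig, camera_index: int = 0) -> Iterator[FrameLike]:
    """Yield landmark frames from a live camera.

    Each captured image is mirrored to selfie view, passed through the
    tracking backend, and converted to :class:`LandmarkFrame` values
    (or :class:`HandAbsent` when no hand is detected).
    """
    try:
        import cv2  # noqa: F401
        import mediapipe  # noqa: F401
    except ImportError as exc:  # pragma: no cover - depends on local install
        raise ImportError(
            "the live adapter needs opencv-python and mediapipe; "
            "install them separately or use a JSONL/simulated stream"
        ) from exc
    raise NotImplementedError(
        "wire your tracking backend here: convert each per-frame result "
        "to a LandmarkFrame (21 normalized [x, y, z] points, handedness, "
        "confidence, timestamp) and yield it"
    )  # pragma: no cover
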