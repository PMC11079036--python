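"""The virtual box-and-blocks world.

Layout geometry, the block lifecycle state machine (RESTING -> GRABBED ->
SCORED | VANISHED), grab/carry/release rules, divider collision, and
out-of-bounds clamping. The arena mirrors the physical test: a box split
into two compartments by a central divider; the subject pinch-grabs one
virtual cube at a time from the source compartment (adjacent to the
assessed hand) and releases it in the target compartment without the
cube touching the divider. A divider contact voids the cube, which
vanishes and is replaced by a fresh spawn; a successful release scores a
point and the cube settles on the compartment floor for the rest of the
trial.

Geometry uses the pixel convention stated in :mod:`arbbt.landmarks`:
origin top-left, y downward, half-open rectangles for containment and
closed rectangles for overlap/clamping.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .landmarks import StreamConfig

BLOCK_COLORS = ("red", "green", "blue", "yellow")


class BlockState(enum.Enum):
    RESTING = "RESTING"
    GRABBED = "GRABBED"
    SCORED = "SCORED"
    VANISHED = "VANISHED"


class EventKind(enum.Enum):
    SPAWN = "SPAWN"
    GRAB = "GRAB"
    DIVIDER_COLLISION = "DIVIDER_COLLISION"
    DROP = "DROP"
    SCORE = "SCORE"
    CLAMP = "CLAMP"


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if self.x1 < self.x0 or self.y1 < self.y0:
            raise ValueError("rectangle must have non-negative extent")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def center(self) -> Tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def contains(self, x: float, y: float) -> bool:
        """Half-open containment."""
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def contains_closed(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    def overlaps(self, other: "Rect") -> bool:
        """Closed-rectangle intersection test (touching edges count)."""
        return (
            self.x0 <= other.x1
            and other.x0 <= self.x1
            and self.y0 <= other.y1
            and other.y0 <= self.y1
        )

    def clamp(self, x: float, y: float) -> Tuple[float, float]:
        """Nearest point of the closed rectangle (component-wise clamp)."""
        return (
            min(max(x, self.x0), self.x1),
            min(max(y, self.y0), self.y1),
        )

    def shrink(self, margin: float) -> "Rect":
        if 2 * margin > min(self.width, self.height):
            raise ValueError("margin larger than rectangle")
        return Rect(
            self.x0 + margin, self.y0 + margin, self.x1 - margin, self.y1 - margin
        )


@dataclass(frozen=True)
class ArenaConfig:
    """Tunables of the virtual box.

    ``blocks_total`` follows the physical test (150 one-inch cubes);
    ``block_half_size`` of 30 px at 720p corresponds to roughly one inch
    at the calibrated ~50 cm camera distance. The divider is a vertical
    band of ``divider_width`` pixels centred on the box midline, rising
    from the box floor to ``divider_top_fraction`` of the box height.
    ``spawn_mode="center"`` pins every spawn to the source-compartment
    centre (deterministic geometry for scripted runs); the default
    ``"uniform"`` draws seeded-uniform positions.
    """

    blocks_total: int = 150
    block_half_size: float = 30.0
    divider_width: float = 24.0
    divider_top_fraction: float = 0.55
    assessed_side: str = "right"
    spawn_margin: float = 40.0
    spawn_mode: str = "uniform"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.blocks_total < 1:
            raise ValueError("blocks_total must be >= 1")
        if self.assessed_side not in ("left", "right"):
            raise ValueError("assessed_side must be 'left' or 'right'")
        if self.spawn_mode not in ("uniform", "center"):
            raise ValueError("spawn_mode must be 'uniform' or 'center'")
        if not 0.0 < self.divider_top_fraction < 1.0:
            raise ValueError("divider_top_fraction must lie in (0, 1)")

    def to_json_dict(self) -> dict:
        return {
            "blocks_total": self.blocks_total,
            "block_half_size": self.block_half_size,
            "divider_width": self.divider_width,
            "divider_top_fraction": self.divider_top_fraction,
            "assessed_side": self.assessed_side,
            "spawn_margin": self.spawn_margin,
            "spawn_mode": self.spawn_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ArenaConfig":
        return cls(**d)


@dataclass(frozen=True)
class BoxLayout:
    """Resolved box geometry: play area, divider band, and compartments.

    ``source`` is the compartment adjacent to the assessed hand (where
    blocks spawn); ``target`` is the opposite one. In a selfie-view
    stream the subject's right hand appears on the right of the image,
    so ``assessed_side="right"`` places the source on the right.
    """

    box: Rect
    divider: Rect
    source: Rect
    target: Rect

    @classmethod
    def build(cls, stream: StreamConfig, cfg: ArenaConfig) -> "BoxLayout":
        box = Rect(0.0, 0.0, float(stream.frame_width), float(stream.frame_height))
        mid = (box.x0 + box.x1) / 2.0
        half_w = cfg.divider_width / 2.0
        divider_top = box.y1 - cfg.divider_top_fraction * box.height
        divider = Rect(mid - half_w, divider_top, mid + half_w, box.y1)
        left = Rect(box.x0, box.y0, mid - half_w, box.y1)
        right = Rect(mid + half_w, box.y0, box.x1, box.y1)
        if cfg.assessed_side == "right":
            source, target = right, left
        else:
            source, target = left, right
        return cls(box=box, divider=divider, source=source, target=target)

    @property
    def divider_top(self) -> float:
        return self.divider.y0


@dataclass
class Block:
    """A virtual cube: axis-aligned square of side 2*half_size."""

    id: int
    color: str
    center: Tuple[float, float]
    half_size: float
    state: BlockState = BlockState.RESTING

    @property
    def rect(self) -> Rect:
        cx, cy = self.center
        h = self.half_size
        return Rect(cx - h, cy - h, cx + h, cy + h)


@dataclass(frozen=True)
class ArenaEvent:
    time: float
    kind: EventKind
    block_id: int
    position: Optional[Tuple[float, float]] = None

    def to_json_dict(self) -> dict:
        return {
            "time": self.time,
            "kind": self.kind.value,
            "block_id": self.block_id,
            "position": list(self.position) if self.position is not None else None,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ArenaEvent":
        pos = d.get("position")
        return cls(
            time=float(d["time"]),
            kind=EventKind(d["kind"]),
            block_id=int(d["block_id"]),
            position=tuple(pos) if pos is not None else None,
        )


@dataclass(frozen=True)
class ArenaObservation:
    """The published view of the arena a closed-loop controller may read:
    the active block (if any), the layout, and the running score."""

    active_block_id: Optional[int]
    active_state: Optional[BlockState]
    active_center: Optional[Tuple[float, float]]
    score: int
    layout: BoxLayout


def clamp_to_box(point: Tuple[float, float], layout: BoxLayout) -> Tuple[float, float]:
    """Component-wise clamp of a point into the box region; identity on
    interior points and idempotent."""
    return layout.box.clamp(point[0], point[1])


class Arena:
    """Block lifecycle state machine over one trial.

    Enforces the single-active-block rule: at most one block is RESTING
    or GRABBED at any instant. Every state change appends a time-ordered
    :class:`ArenaEvent`; replaying the same landmark stream with the same
    seed reproduces the event log exactly.
    """

    def __init__(
        self,
        layout: BoxLayout,
        cfg: ArenaConfig,
        seed: Optional[int] = None,
    ) -> None:
        self.layout = layout
        self.cfg = cfg
        effective_seed = cfg.seed if cfg.seed is not None else seed
        self.rng = np.random.default_rng(effective_seed)
        self.active: Optional[Block] = None
        self.spawned = 0
        self.scored_blocks: List[Block] = []
        self.vanished = 0
        self.score = 0
        self.events: List[ArenaEvent] = []

    # -- event plumbing ----------------------------------------------------

    def _emit(
        self,
        time: float,
        kind: EventKind,
        block_id: int,
        position: Optional[Tuple[float, float]],
    ) -> None:
        self.events.append(
            ArenaEvent(time=time, kind=kind, block_id=block_id, position=position)
        )

    def count_events(self, kind: EventKind) -> int:
        return sum(1 for e in self.events if e.kind is kind)

    # -- operations --------------------------------------------------------

    def spawn_block(self, t: float) -> Optional[Block]:
        """Spawn the next block at a seeded position in the source
        compartment, or return None when all blocks are exhausted."""
        if self.active is not None and self.active.state in (
            BlockState.RESTING,
            BlockState.GRABBED,
        ):
            raise RuntimeError("single-block rule: a block is already active")
        if self.spawned >= self.cfg.blocks_total:
            return None
        region = self.layout.source.shrink(self.cfg.spawn_margin)
        if self.cfg.spawn_mode == "center":
            pos = region.center
        else:
            pos = (
                float(self.rng.uniform(region.x0, region.x1)),
                float(self.rng.uniform(region.y0, region.y1)),
            )
        color = BLOCK_COLORS[int(self.rng.integers(len(BLOCK_COLORS)))]
        block = Block(
            id=self.spawned + 1,
            color=color,
            center=pos,
            half_size=self.cfg.block_half_size,
        )
        self.spawned += 1
        self.active = block
        self._emit(t, EventKind.SPAWN, block.id, pos)
        return block

    def try_grab(
        self,
        t: float,
        thumb: Tuple[float, float],
        index: Tuple[float, float],
        pinch_is_closed: bool,
    ) -> bool:
        """Grab iff BOTH fingertips lie within the block and the pinch is
        closed. A failed grab is a no-op."""
        block = self.active
        if block is None or block.state is not BlockState.RESTING:
            return False
        r = block.rect
        if (
            pinch_is_closed
            and r.contains_closed(thumb[0], thumb[1])
            and r.contains_closed(index[0], index[1])
        ):
            block.state = BlockState.GRABBED
            self._emit(t, EventKind.GRAB, block.id, block.center)
            return True
        return False

    def carry(
        self,
        t: float,
        thumb: Tuple[float, float],
        index: Tuple[float, float],
    ) -> Tuple[float, float]:
        """Move the grabbed block to the fingertip midpoint, clamped into
        the box, then check divider collision (which voids the block)."""
        block = self.active
        if block is None or block.state is not BlockState.GRABBED:
            raise RuntimeError("carry requires a grabbed block")
        raw = ((thumb[0] + index[0]) / 2.0, (thumb[1] + index[1]) / 2.0)
        clamped = clamp_to_box(raw, self.layout)
        if clamped != raw:
            self._emit(t, EventKind.CLAMP, block.id, clamped)
        block.center = clamped
        if block.rect.overlaps(self.layout.divider):
            block.state = BlockState.VANISHED
            self.vanished += 1
            self._emit(t, EventKind.DIVIDER_COLLISION, block.id, clamped)
            self.active = None
        return clamped

    def try_release(
        self,
        t: float,
        thumb: Tuple[float, float],
        index: Tuple[float, float],
    ) -> str:
        """Release the grabbed block at the fingertip midpoint.

        Inside the target compartment the block SCOREs, settles on the
        compartment floor, and persists for the rest of the trial;
        anywhere else it returns to RESTING at the (clamped) drop point
        and stays grabbable. Returns "scored" or "dropped".
        """
        block = self.active
        if block is None or block.state is not BlockState.GRABBED:
            raise RuntimeError("release requires a grabbed block")
        raw = ((thumb[0] + index[0]) / 2.0, (thumb[1] + index[1]) / 2.0)
        drop = clamp_to_box(raw, self.layout)
        if self.layout.target.contains(drop[0], drop[1]):
            settled = (drop[0], self.layout.box.y1 - block.half_size)
            block.center = settled
            block.state = BlockState.SCORED
            self.score += 1
            self.scored_blocks.append(block)
            self._emit(t, EventKind.SCORE, block.id, settled)
            self.active = None
            return "scored"
        block.center = drop
        block.state = BlockState.RESTING
        self._emit(t, EventKind.DROP, block.id, drop)
        return "dropped"

    # -- bookkeeping -------------------------------------------------------

    @property
    def unspawned(self) -> int:
        return self.cfg.blocks_total - self.spawned

    def conservation_ok(self) -> bool:
        """SCORED + VANISHED + active + unspawned == blocks_total."""
        active = 1 if self.active is not None else 0
        return (
            len(self.scored_blocks) + self.vanished + active + self.unspawned
            == self.cfg.blocks_total
        )

    def observation(self) -> ArenaObservation:
        b = self.active
        return ArenaObservation(
            active_block_id=b.id if b is not None else None,
            active_state=b.state if b is not None else None,
            active_center=b.center if b is not None else None,
            score=self.score,
            layout=self.layout,
        )
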