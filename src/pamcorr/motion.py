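"""Raster-scan motion-artifact injection.

In raster-scanned OR-PAM the fast axis (X, within a row) is acquired in
milliseconds while the slow axis (Y, row to row) takes seconds, so breathing
and heartbeat displace whole blocks of consecutive rows.  A corrupted image
therefore looks like the clean image with some row blocks sampled from a
shifted location: vertical tears (dy), horizontal tears (dx), or oblique
tears when the displacement ramps linearly across the block.

Conventions: row index = slow axis (Y), column = fast axis (X), origin
top-left, 0-based indices, row ranges half-open.  Displacements are integer
pixels; the corrupted image samples FROM the clean image at
``(y + dy, x + dx)`` (the sample moves under a fixed scan trajectory), with
out-of-bounds reads replaced by a configurable fill value (default 0, the
dark MAP background).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .phantom import PhantomImage

__all__ = [
    "MotionEvent",
    "MotionProfile",
    "apply_motion",
    "apply_motion_array",
    "random_motion_profile",
    "profile_to_json",
    "profile_from_json",
]


@dataclass(frozen=True)
class MotionEvent:
    """One block displacement: rows [start_row, end_row) sample from (+dy, +dx).

    With ``ramp`` set, the displacement is linearly interpolated from 0 at
    ``start_row`` to (dy, dx) at the last affected row, producing an oblique
    tear; otherwise it is constant over the block.
    """

    start_row: int
    end_row: int
    dy: int
    dx: int
    ramp: bool = False

    def __post_init__(self) -> None:
        if self.start_row < 0 or self.end_row <= self.start_row:
            raise ValueError(
                f"invalid row range [{self.start_row}, {self.end_row})"
            )
        if self.dy == 0 and self.dx == 0:
            raise ValueError("a motion event must have (dy, dx) != (0, 0)")

    def displacement_at(self, row: int) -> tuple[int, int]:
        """Integer (dy, dx) applied at ``row`` (must lie inside the event)."""
        if not self.start_row <= row < self.end_row:
            raise ValueError(f"row {row} outside event rows")
        if not self.ramp or self.end_row - self.start_row == 1:
            return self.dy, self.dx
        t = (row - self.start_row) / (self.end_row - 1 - self.start_row)
        return int(round(t * self.dy)), int(round(t * self.dx))


@dataclass(frozen=True)
class MotionProfile:
    """Ordered, non-overlapping motion events plus the out-of-bounds fill value."""

    events: tuple[MotionEvent, ...]
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        prev_end = None
        for ev in events:
            if prev_end is not None and ev.start_row < prev_end:
                raise ValueError("motion events must be sorted and disjoint")
            prev_end = ev.end_row

    def validate_for_height(self, height: int) -> None:
        if self.events and self.events[-1].end_row > height:
            raise ValueError(
                f"event rows exceed image height {height}"
            )

    def negated(self) -> "MotionProfile":
        """Profile with every displacement sign-flipped (approximate inverse)."""
        return MotionProfile(
            events=tuple(
                MotionEvent(e.start_row, e.end_row, -e.dy, -e.dx, e.ramp)
                for e in self.events
            ),
            fill_value=self.fill_value,
        )


def apply_motion_array(clean: np.ndarray, profile: MotionProfile) -> np.ndarray:
    """Apply a motion profile to a bare 2-D array; the input is never mutated."""
    clean = np.asarray(clean)
    if clean.ndim != 2:
        raise ValueError("motion corruption expects a 2-D image")
    height, width = clean.shape
    profile.validate_for_height(height)
    out = clean.copy()
    for ev in profile.events:
        for y in range(ev.start_row, ev.end_row):
            dy, dx = ev.displacement_at(y)
            src_y = y + dy
            if not 0 <= src_y < height:
                out[y, :] = profile.fill_value
                continue
            row = np.full(width, profile.fill_value, dtype=clean.dtype)
            lo = max(0, -dx)
            hi = min(width, width - dx)
            if lo < hi:
                row[lo:hi] = clean[src_y, lo + dx : hi + dx]
            out[y, :] = row
    return out


def apply_motion(clean, profile: MotionProfile):
    """Apply a motion profile to a PhantomImage, MAPImage or plain array.

    Rows outside all events are copied unchanged; the return value has the
    same type as the input.
    """
    from .acquisition import MAPImage

    if isinstance(clean, PhantomImage):
        return PhantomImage(
            pixels=apply_motion_array(clean.pixels, profile),
            pixel_size_um=clean.pixel_size_um,
        )
    if isinstance(clean, MAPImage):
        return MAPImage(pixels=apply_motion_array(clean.pixels, profile))
    return apply_motion_array(clean, profile)


def random_motion_profile(
    height: int,
    n_events_range: tuple[int, int],
    block_len_range: tuple[int, int],
    max_dy: int,
    max_dx: int,
    ramp_prob: float = 0.0,
    seed: int = 0,
    fill_value: float = 0.0,
) -> MotionProfile:
    """Draw a random, non-overlapping motion profile.

    The number of events is uniform on ``n_events_range`` (inclusive), block
    lengths uniform on ``block_len_range`` (inclusive), and each displacement
    is uniform over the integer grid [-max_dy, max_dy] x [-max_dx, max_dx]
    with (0, 0) rejected.  Each event is ramped with probability
    ``ramp_prob``.  Deterministic under ``seed``.
    """
    if n_events_range[0] < 0 or n_events_range[1] < n_events_range[0]:
        raise ValueError("n_events_range must be a non-empty non-negative range")
    if block_len_range[0] < 1 or block_len_range[1] < block_len_range[0]:
        raise ValueError("block_len_range must be a non-empty positive range")
    if max_dy < 0 or max_dx < 0 or max_dy + max_dx < 1:
        raise ValueError("need max_dy + max_dx >= 1 with non-negative bounds")

    rng = np.random.default_rng(seed)
    n_events = int(rng.integers(n_events_range[0], n_events_range[1] + 1))
    if n_events == 0:
        return MotionProfile(events=(), fill_value=fill_value)
    if n_events * block_len_range[0] > height:
        raise ValueError(
            f"cannot fit {n_events} events of length >= "
            f"{block_len_range[0]} into {height} rows"
        )

    lengths = rng.integers(
        block_len_range[0], block_len_range[1] + 1, size=n_events
    )
    # shrink greedily if the draw cannot fit, then place blocks by
    # distributing the leftover rows as random gaps
    while lengths.sum() > height:
        lengths[np.argmax(lengths)] -= 1
    slack = height - int(lengths.sum())
    cuts = np.sort(rng.integers(0, slack + 1, size=n_events))
    events = []
    offset = 0
    for i in range(n_events):
        start = int(cuts[i]) + offset
        end = start + int(lengths[i])
        offset = end - int(cuts[i])
        dy, dx = 0, 0
        while dy == 0 and dx == 0:
            dy = int(rng.integers(-max_dy, max_dy + 1))
            dx = int(rng.integers(-max_dx, max_dx + 1))
        ramp = bool(rng.uniform() < ramp_prob)
        events.append(MotionEvent(start, end, dy, dx, ramp))
    profile = MotionProfile(events=tuple(events), fill_value=fill_value)
    profile.validate_for_height(height)
    return profile


def profile_to_json(profile: MotionProfile, path: str | Path | None = None) -> str:
    """Serialize a profile to JSON; optionally write it to ``path``."""
    doc = {
        "fill_value": profile.fill_value,
        "events": [
            {
                "start_row": e.start_row,
                "end_row": e.end_row,
                "dy": e.dy,
                "dx": e.dx,
                "ramp": e.ramp,
            }
            for e in profile.events
        ],
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def profile_from_json(source: str | Path) -> MotionProfile:
    """Load a profile from a JSON string or file path."""
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("{")
    ):
        text = Path(source).read_text()
    else:
        text = source
    doc = json.loads(text)
    events = tuple(
        MotionEvent(
            int(e["start_row"]),
            int(e["end_row"]),
            int(e["dy"]),
            int(e["dx"]),
            bool(e.get("ramp", False)),
        )
        for e in doc["events"]
    )
    return MotionProfile(events=events, fill_value=float(doc.get("fill_value", 0.0)))
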