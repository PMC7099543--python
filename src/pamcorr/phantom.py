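"""Synthetic ground-truth phantoms for OR-PAM maximum-amplitude-projection images.

OR-PAM maps of rodent cortical vasculature show smooth, curvilinear vessels of
varying caliber on a dark background.  This module generates seeded stand-ins
for such images — vessel networks built from second-order random-walk
centerlines with Gaussian cross-sections, and simple periodic grid targets —
plus paired (corrupted, clean) training datasets produced by the raster-scan
motion model in :mod:`pamcorr.motion`.

All generators are deterministic under their seed: identical arguments produce
bit-identical pixel arrays.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "PhantomImage",
    "PhantomConfig",
    "DatasetMotionConfig",
    "TrainingPair",
    "generate_vessel_phantom",
    "generate_grid_phantom",
    "make_training_dataset",
    "write_image",
    "read_image",
    "write_manifest",
]

# FWHM -> sigma conversion for the Gaussian vessel cross-section
_FWHM_TO_SIGMA = 1.0 / 2.355


@dataclass(frozen=True)
class PhantomImage:
    """Clean ground-truth 2-D MAP image.

    Rows index the slow scan axis (Y), columns the fast scan axis (X);
    intensities are normalized optical absorption in [0, 1].
    ``pixel_size_um`` is carried as metadata only.
    """

    pixels: np.ndarray
    pixel_size_um: float = 2.5

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"phantom pixels must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("phantom pixels must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("phantom pixel values must lie in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _walk_centerline(
    rng: np.random.Generator,
    height: int,
    width: int,
    tortuosity: float,
    max_steps: int,
    start: np.ndarray | None = None,
    direction: float | None = None,
) -> np.ndarray:
    """Second-order random-walk centerline.

    The heading angle performs a random walk whose per-step turn is bounded by
    ``tortuosity`` (0 = straight line, 1 = strongly meandering); positions
    advance one pixel per step and the walk stops when it leaves the frame.
    """
    if start is None:
        # start on a random edge so vessels traverse the field of view
        edge = rng.integers(4)
        if edge == 0:
            pos = np.array([0.0, rng.uniform(0, width - 1)])
        elif edge == 1:
            pos = np.array([height - 1.0, rng.uniform(0, width - 1)])
        elif edge == 2:
            pos = np.array([rng.uniform(0, height - 1), 0.0])
        else:
            pos = np.array([rng.uniform(0, height - 1), width - 1.0])
        center = np.array([(height - 1) / 2.0, (width - 1) / 2.0])
        inward = center - pos
        theta = float(np.arctan2(inward[0], inward[1]) + rng.normal(0.0, 0.4))
    else:
        pos = start.astype(np.float64).copy()
        theta = float(direction if direction is not None else rng.uniform(-np.pi, np.pi))

    max_turn = 0.35 * tortuosity
    pts = [pos.copy()]
    omega = 0.0
    for _ in range(max_steps):
        # second-order: the turn rate itself diffuses, giving smooth curvature
        omega = 0.7 * omega + rng.normal(0.0, max_turn)
        omega = float(np.clip(omega, -max_turn, max_turn))
        theta += omega
        pos = pos + np.array([np.sin(theta), np.cos(theta)])
        if not (0 <= pos[0] <= height - 1 and 0 <= pos[1] <= width - 1):
            break
        pts.append(pos.copy())
    return np.array(pts)


def _rasterize_tube(
    canvas: np.ndarray, centerline: np.ndarray, fwhm: float, peak: float
) -> None:
    """Stamp a Gaussian cross-section along the centerline, compositing by max."""
    if len(centerline) == 0:
        return
    height, width = canvas.shape
    sigma = max(fwhm * _FWHM_TO_SIGMA, 0.5)
    radius = int(np.ceil(3.0 * sigma))
    for cy, cx in centerline:
        y0 = max(int(np.floor(cy)) - radius, 0)
        y1 = min(int(np.ceil(cy)) + radius + 1, height)
        x0 = max(int(np.floor(cx)) - radius, 0)
        x1 = min(int(np.ceil(cx)) + radius + 1, width)
        if y0 >= y1 or x0 >= x1:
            continue
        yy = np.arange(y0, y1, dtype=np.float64)[:, None]
        xx = np.arange(x0, x1, dtype=np.float64)[None, :]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        stamp = peak * np.exp(-d2 / (2.0 * sigma * sigma))
        patch = canvas[y0:y1, x0:x1]
        np.maximum(patch, stamp, out=patch)


def generate_vessel_phantom(
    height: int,
    width: int,
    n_vessels: int,
    vessel_width_range: tuple[float, float] = (2.0, 4.0),
    tortuosity: float = 0.3,
    seed: int = 0,
    branch_prob: float = 0.3,
    pixel_size_um: float = 2.5,
) -> PhantomImage:
    """Generate a seeded vessel-network phantom.

    Each vessel is a smooth random-walk centerline rasterized with a Gaussian
    cross-section (sigma = width / 2.355, i.e. width is the FWHM); per-vessel
    peak intensity is drawn uniformly from [0.5, 1.0].  Overlapping vessels
    composite by maximum (a MAP is itself a max projection) and the final
    image is max-normalized to 1.0.  With probability ``branch_prob`` a vessel
    spawns one thinner side branch.

    Raises ``ValueError`` for dimensions < 16, negative vessel counts, or an
    empty/invalid width range.
    """
    if height < 16 or width < 16:
        raise ValueError("phantom dimensions must be at least 16x16")
    if n_vessels < 0:
        raise ValueError("n_vessels must be non-negative")
    lo, hi = float(vessel_width_range[0]), float(vessel_width_range[1])
    if lo < 1 or hi < lo:
        raise ValueError("vessel_width_range must satisfy 1 <= min <= max")
    if not 0.0 <= tortuosity <= 1.0:
        raise ValueError("tortuosity must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    canvas = np.zeros((height, width), dtype=np.float64)
    max_steps = 2 * (height + width)
    for _ in range(n_vessels):
        fwhm = rng.uniform(lo, hi)
        peak = rng.uniform(0.5, 1.0)
        line = _walk_centerline(rng, height, width, tortuosity, max_steps)
        _rasterize_tube(canvas, line, fwhm, peak)
        if len(line) > 8 and rng.uniform() < branch_prob:
            j = int(rng.integers(4, len(line) - 4))
            seg = line[j] - line[j - 1]
            theta = float(np.arctan2(seg[0], seg[1]))
            theta += rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.2)
            branch = _walk_centerline(
                rng, height, width, tortuosity, max_steps // 2,
                start=line[j], direction=theta,
            )
            _rasterize_tube(canvas, branch, max(fwhm * 0.7, 1.0), peak)

    peak_val = canvas.max()
    if peak_val > 0:
        canvas /= peak_val
    return PhantomImage(pixels=canvas, pixel_size_um=pixel_size_um)


def generate_grid_phantom(
    height: int,
    width: int,
    line_spacing: int,
    line_width: int,
    pixel_size_um: float = 2.5,
) -> PhantomImage:
    """Periodic bright horizontal + vertical lines on a zero background.

    Rows r with ``r % line_spacing < line_width`` (and likewise columns) are
    set to 1.0.  Deterministic; no randomness involved.
    """
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    if line_spacing <= line_width:
        raise ValueError("line_spacing must exceed line_width")
    if height < 16 or width < 16:
        raise ValueError("phantom dimensions must be at least 16x16")
    rows = (np.arange(height) % line_spacing) < line_width
    cols = (np.arange(width) % line_spacing) < line_width
    canvas = np.zeros((height, width), dtype=np.float64)
    canvas[rows, :] = 1.0
    canvas[:, cols] = 1.0
    return PhantomImage(pixels=canvas, pixel_size_um=pixel_size_um)


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the vessel-phantom generator used for dataset creation."""

    n_vessels: int = 8
    vessel_width_range: tuple[float, float] = (2.0, 6.0)
    tortuosity: float = 0.4
    branch_prob: float = 0.3


@dataclass(frozen=True)
class DatasetMotionConfig:
    """Motion-corruption parameters for training-pair generation.

    ``corrupt_prob`` is the probability that a pair receives a (non-empty)
    motion profile at all; a pair that does not is emitted with
    corrupted == clean.
    """

    n_events_range: tuple[int, int] = (1, 3)
    block_len_range: tuple[int, int] = (2, 8)
    max_dy: int = 4
    max_dx: int = 4
    ramp_prob: float = 0.25
    fill_value: float = 0.0
    corrupt_prob: float = 1.0


class TrainingPair(NamedTuple):
    """A (corrupted, clean) image pair plus the profile that produced it."""

    corrupted: PhantomImage
    clean: PhantomImage
    profile: "object"  # MotionProfile; typed loosely to avoid a cyclic import


def _subseed(ss: np.random.SeedSequence) -> int:
    """Collapse a spawned SeedSequence to a non-negative 31-bit integer seed."""
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def make_training_dataset(
    n_pairs: int,
    image_shape: tuple[int, int],
    phantom_config: PhantomConfig | None = None,
    motion_config: DatasetMotionConfig | None = None,
    seed: int = 0,
) -> list[TrainingPair]:
    """Generate ``n_pairs`` (corrupted, clean) phantom pairs.

    Per-pair sub-seeds are derived from the master seed with numpy's
    splittable ``SeedSequence.spawn`` scheme, so the dataset is reproducible
    and pairs are independent.  The clean member is never mutated by the
    corruption step.
    """
    from . import motion as motion_mod

    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    phantom_config = phantom_config or PhantomConfig()
    motion_config = motion_config or DatasetMotionConfig()
    height, width = image_shape

    master = np.random.SeedSequence(seed)
    children = master.spawn(n_pairs)
    pairs: list[TrainingPair] = []
    for child in children:
        ph_ss, mo_ss, gate_ss = child.spawn(3)
        clean = generate_vessel_phantom(
            height,
            width,
            phantom_config.n_vessels,
            phantom_config.vessel_width_range,
            phantom_config.tortuosity,
            seed=_subseed(ph_ss),
            branch_prob=phantom_config.branch_prob,
        )
        gate = np.random.default_rng(gate_ss).uniform()
        if gate < motion_config.corrupt_prob and motion_config.n_events_range[1] > 0:
            profile = motion_mod.random_motion_profile(
                height,
                motion_config.n_events_range,
                motion_config.block_len_range,
                motion_config.max_dy,
                motion_config.max_dx,
                motion_config.ramp_prob,
                seed=_subseed(mo_ss),
                fill_value=motion_config.fill_value,
            )
        else:
            profile = motion_mod.MotionProfile(
                events=(), fill_value=motion_config.fill_value
            )
        corrupted = motion_mod.apply_motion(clean, profile)
        pairs.append(TrainingPair(corrupted=corrupted, clean=clean, profile=profile))
    return pairs


# ---------------------------------------------------------------------------
# Image IO: 8/16-bit grayscale PNG, 32-bit float TIFF


def write_image(path: str | Path, image: PhantomImage | np.ndarray, bit_depth: int = 16) -> None:
    """Write a [0, 1] image as grayscale PNG (8 or 16 bit) or float32 TIFF.

    The format is chosen from the file extension (.png / .tif / .tiff).
    """
    path = Path(path)
    px = image.pixels if isinstance(image, PhantomImage) else np.asarray(image, dtype=np.float64)
    suffix = path.suffix.lower()
    if suffix == ".png":
        if bit_depth == 8:
            arr = np.round(np.clip(px, 0, 1) * 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(path)
        elif bit_depth == 16:
            arr = np.round(np.clip(px, 0, 1) * 65535).astype(np.uint16)
            Image.fromarray(arr).save(path)
        else:
            raise ValueError("PNG bit_depth must be 8 or 16")
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, px.astype(np.float32))
    else:
        raise ValueError(f"unsupported image extension: {suffix!r}")


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image back to a float64 array scaled to [0, 1]."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        img = Image.open(path)
        arr = np.asarray(img, dtype=np.float64)
        if img.mode == "I;16" or arr.max() > 255:
            return arr / 65535.0
        return arr / 255.0
    if suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=np.float64)
    raise ValueError(f"unsupported image extension: {suffix!r}")


def write_manifest(
    path: str | Path,
    entries: Sequence[dict],
    seed: int,
    phantom_config: PhantomConfig,
    motion_config: DatasetMotionConfig,
) -> None:
    """Write a JSON dataset manifest (file paths, seeds, per-pair motion parameters)."""
    doc = {
        "seed": seed,
        "phantom_config": dataclasses.asdict(phantom_config),
        "motion_config": dataclasses.asdict(motion_config),
        "pairs": list(entries),
    }
    Path(path).write_text(json.dumps(doc, indent=2))
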