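"""Frame-to-frame centrosome tracking.

Each centrosome (spindle pole) is tracked independently: the position found
in the previous frame is projected onto the current frame, a small boundary
box is placed around the projection (shifted horizontally toward the side
the centrosome is expected to move), and the scanning-circle search of
:mod:`centrotrack.granularity` picks the pixel of minimal mean granularity
inside the box.  The anterior centrosome is best tracked in forward
(chronological) direction, the posterior one in backward direction; both
defaults come from a hold-out grid-search optimization.

All window sizes scale with the embryo height so that movies of different
pixel resolution can be processed with the same relative parameters:

* boundary-box height  ``hbb = hbb_rel * 4%`` of embryo height
  (times a frame-rate multiplier for slowly acquired movies),
* boundary-box width   ``wbb = hbb / 2``,
* scanning-circle diameter ``dsc = dsc_rel * 12%`` of embryo height,
* granularity disc ~ 1% of embryo height.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .granularity import BoundaryBox, GranularitySpec, scan_minimum
from .movie import EmbryoGeometry, Movie

__all__ = [
    "TrackingParams",
    "PixelSizes",
    "SeedPair",
    "CentrosomeTrack",
    "default_params",
    "scale_params",
    "make_boundary_box",
    "track_centrosome",
    "track_pair",
]

Role = Literal["anterior", "posterior"]
Direction = Literal["forward", "backward"]

#: base sizes relative to the embryo height
HBB_BASE_FRACTION = 0.04
DSC_BASE_FRACTION = 0.12

#: optimized relative parameters: (hbb_rel, dsc_rel, direction)
DEFAULTS: dict[str, tuple[float, float, str]] = {
    "anterior": (1.125, 1.250, "forward"),
    "posterior": (1.375, 1.125, "backward"),
}


@dataclass(frozen=True)
class TrackingParams:
    """Geometric and directional knobs of the tracking engine.

    ``hbb_rel`` and ``dsc_rel`` are dimensionless factors on the 4% / 12%
    embryo-height base sizes.  ``framerate_multiplier`` enlarges the
    boundary box for low acquisition frequencies (x3 was needed at
    0.2 frames/s versus the standard 2 frames/s).  ``box_split`` is the
    fraction of the boundary-box width allocated on the side of the
    centrosome's expected motion.
    """

    role: str = "anterior"
    hbb_rel: float = 1.125
    dsc_rel: float = 1.250
    direction: str = "forward"
    framerate_multiplier: float = 1.0
    gc_fraction: float = 0.01
    box_split: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.role not in ("anterior", "posterior"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.hbb_rel <= 0 or self.dsc_rel <= 0:
            raise ValueError("hbb_rel and dsc_rel must be positive")
        if self.framerate_multiplier < 1:
            raise ValueError("framerate_multiplier must be >= 1")
        if not 0.0 <= self.box_split <= 1.0:
            raise ValueError("box_split must lie in [0, 1]")


def default_params(role: str, **overrides) -> TrackingParams:
    """Optimized defaults for a role: anterior (1.125, 1.250, forward),
    posterior (1.375, 1.125, backward)."""
    hbb_rel, dsc_rel, direction = DEFAULTS[role]
    kw = dict(role=role, hbb_rel=hbb_rel, dsc_rel=dsc_rel, direction=direction)
    kw.update(overrides)
    return TrackingParams(**kw)


@dataclass(frozen=True)
class PixelSizes:
    """Absolute engine window sizes in pixels for one movie."""

    hbb: int
    wbb: int
    dsc: int
    gc: int


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _round_odd(x: float) -> int:
    """Nearest odd integer (ties toward the larger odd)."""
    return 2 * _round_half_up((x - 1.0) / 2.0) + 1


def scale_params(
    params: TrackingParams,
    geometry: EmbryoGeometry,
    frame_shape: tuple[int, int] | None = None,
) -> PixelSizes:
    """Convert relative parameters to absolute pixel sizes.

    hbb = round(hbb_rel * 4% * embryo_height * framerate_multiplier), min 3;
    wbb = round(hbb / 2), min 1; dsc and gc are rounded to the nearest odd
    integer (min 3) so the discs have a unique centre pixel.
    """
    h = geometry.embryo_height
    hbb = max(3, _round_half_up(params.hbb_rel * HBB_BASE_FRACTION * h * params.framerate_multiplier))
    wbb = max(1, _round_half_up(hbb / 2.0))
    dsc = max(3, _round_odd(params.dsc_rel * DSC_BASE_FRACTION * h))
    gc = max(3, _round_odd(params.gc_fraction * h))
    if frame_shape is not None:
        fh, fw = frame_shape
        if hbb > fh or dsc > fh or wbb > fw or dsc > fw:
            raise ValueError(
                f"scaled sizes (hbb={hbb}, wbb={wbb}, dsc={dsc}) exceed the "
                f"{fw}x{fh} frame for embryo_height={geometry.embryo_height}"
            )
    return PixelSizes(hbb=hbb, wbb=wbb, dsc=dsc, gc=gc)


def _expected_motion_sign(role: str, direction: str) -> int:
    """-1 if the centrosome is expected to move leftward (anteriorward) in
    the tracked direction of time, +1 for rightward.

    In forward time the anterior centrosome drifts anteriorward (left) and
    the posterior centrosome posteriorward (right); tracking backward
    reverses the apparent motion.
    """
    sign = -1 if role == "anterior" else +1
    if direction == "backward":
        sign = -sign
    return sign


def make_boundary_box(
    prev_position: tuple[int, int],
    params: TrackingParams,
    sizes: PixelSizes,
    frame_shape: tuple[int, int],
) -> BoundaryBox:
    """Search box for the next frame, centred vertically on the previous
    position and shifted horizontally toward the expected motion.

    The box spans ``wbb`` columns including the previous x; the fraction
    ``box_split`` of the remaining columns is placed on the expected-motion
    side.  The result is clipped to the frame (an error is raised if nothing
    remains, i.e. the seed sits at the frame edge).
    """
    x, y = prev_position
    h, w = frame_shape
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"previous position ({x}, {y}) outside the {w}x{h} frame")
    y_min = y - sizes.hbb // 2
    y_max = y_min + sizes.hbb - 1
    spread = sizes.wbb - 1
    major = _round_half_up(params.box_split * spread)
    minor = spread - major
    if _expected_motion_sign(params.role, params.direction) < 0:
        x_min, x_max = x - major, x + minor
    else:
        x_min, x_max = x - minor, x + major
    return BoundaryBox(x_min, x_max, y_min, y_max).clip(frame_shape)


@dataclass(frozen=True)
class CentrosomeTrack:
    """Per-frame integer pixel positions of one centrosome.

    ``entries`` is an ordered tuple of ``(frame_index, x, y)`` sorted by
    ascending frame index regardless of the tracking direction.
    """

    role: str
    entries: tuple[tuple[int, int, int], ...]
    direction: str
    params: TrackingParams

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of (x, y) pixel positions sorted by frame."""
        return np.array([(e[1], e[2]) for e in self.entries], dtype=int)

    def __len__(self) -> int:
        return len(self.entries)


def _frame_order(frame_range: tuple[int, int], direction: str) -> Sequence[int]:
    start, end = frame_range
    if start > end:
        raise ValueError(f"frame range ({start}, {end}) is reversed")
    order = list(range(start, end + 1))
    return order if direction == "forward" else order[::-1]


def track_centrosome(
    movie: Movie,
    seed: tuple[int, int],
    params: TrackingParams,
    geometry: EmbryoGeometry,
    frame_range: tuple[int, int] | None = None,
) -> CentrosomeTrack:
    """Track one centrosome over ``frame_range`` (inclusive).

    The seed is the user-clicked position on the first processed frame
    (first frame of the range for forward tracking, last for backward).  The
    seed frame itself is re-scanned — the seed only centres the first search
    box — so small clicking errors are corrected by the engine.  Entries are
    returned sorted by ascending frame index.
    """
    if movie.n_frames < 2:
        raise ValueError("movie must have at least 2 frames")
    if frame_range is None:
        frame_range = (0, movie.n_frames - 1)
    start, end = frame_range
    if not (0 <= start <= end < movie.n_frames):
        raise ValueError(f"frame range ({start}, {end}) outside movie of {movie.n_frames} frames")

    sizes = scale_params(params, geometry, (movie.height, movie.width))
    spec = GranularitySpec(gc_diameter=sizes.gc)
    order = _frame_order(frame_range, params.direction)

    x, y = int(seed[0]), int(seed[1])
    if not (0 <= x < movie.width and 0 <= y < movie.height):
        raise ValueError(f"seed ({x}, {y}) outside the frame")

    found: dict[int, tuple[int, int]] = {}
    prev = (x, y)
    for idx in order:
        box = make_boundary_box(prev, params, sizes, (movie.height, movie.width))
        try:
            result = scan_minimum(movie.frame(idx), box, sizes.dsc, spec)
        except ValueError as exc:
            raise RuntimeError(f"tracking failed at frame {idx} ({params.role}): {exc}") from exc
        prev = result.position
        found[idx] = result.position

    entries = tuple((i, found[i][0], found[i][1]) for i in sorted(found))
    return CentrosomeTrack(role=params.role, entries=entries, direction=params.direction, params=params)


@dataclass(frozen=True)
class SeedPair:
    """User-clicked positions of one centrosome on the first and last
    analyzed frame (forward tracking starts from the former, backward from
    the latter)."""

    first_frame_position: tuple[int, int]
    last_frame_position: tuple[int, int]


def track_pair(
    movie: Movie,
    seeds: dict[str, SeedPair],
    geometry: EmbryoGeometry,
    params: dict[str, TrackingParams] | None = None,
    frame_range: tuple[int, int] | None = None,
) -> tuple[CentrosomeTrack, CentrosomeTrack]:
    """Track the anterior and posterior centrosome independently.

    With no overrides the anterior runs forward with (1.125, 1.250) and the
    posterior backward with (1.375, 1.125).  Returns (anterior, posterior)
    tracks covering the same frame range.
    """
    params = params or {}
    tracks = []
    for role in ("anterior", "posterior"):
        p = params.get(role, default_params(role))
        if p.role != role:
            p = replace(p, role=role)
        seed_pair = seeds[role]
        seed = (
            seed_pair.first_frame_position
            if p.direction == "forward"
            else seed_pair.last_frame_position
        )
        try:
            tracks.append(track_centrosome(movie, seed, p, geometry, frame_range))
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"{role} centrosome: {exc}") from exc
    return tracks[0], tracks[1]
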