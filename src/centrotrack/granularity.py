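"""Local pixel-variance ("granularity") fields and scanning-circle search.

In DIC images of one-cell nematode embryos the cytoplasm is filled with yolk
granules and shows a high local variance of pixel values, while centrosomes
appear as smooth circular regions of low variance.  The tracker exploits this
contrast: a candidate centrosome position is scored by the mean granularity
inside a scanning circle, and the position with minimal mean granularity
within a constrained search box wins.

Conventions fixed here and relied on by every caller and test:

* a *disc* of diameter ``d`` centred on pixel ``(x, y)`` contains every pixel
  whose centre lies at Euclidean distance ``<= d / 2`` from ``(x, y)``;
* granularity is the *population* variance (divide by ``n``) of the
  intensities inside the small granularity disc;
* discs and boxes are clipped to the frame; partially clipped discs use only
  in-frame pixels;
* ties in the scan are broken by the first minimal pixel in row-major order
  (top-to-bottom, left-to-right) of the search box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BoundaryBox",
    "GranularitySpec",
    "GranularityField",
    "ScanResult",
    "disc_mask",
    "disc_offsets",
    "disc_variance",
    "granularity_field",
    "focus_region",
    "circle_mean_score",
    "scan_minimum",
]


@dataclass(frozen=True)
class GranularitySpec:
    """Size of the small disc over which pixel-value variance is computed.

    The granularity disc is about 1% of the embryo height; sizes are rounded
    to the nearest odd integer (>= 3) upstream so the disc has a unique
    centre pixel.
    """

    gc_diameter: int = 3

    def __post_init__(self) -> None:
        if self.gc_diameter < 1:
            raise ValueError("gc_diameter must be >= 1 pixel")


@dataclass(frozen=True)
class BoundaryBox:
    """Inclusive pixel bounds of a rectangular search region."""

    x_min: int
    x_max: int
    y_min: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError(f"degenerate boundary box {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min + 1

    @property
    def height(self) -> int:
        return self.y_max - self.y_min + 1

    def clip(self, frame_shape: tuple[int, int]) -> "BoundaryBox":
        """Clip to the frame; raises if nothing remains."""
        h, w = frame_shape
        x_min = max(self.x_min, 0)
        y_min = max(self.y_min, 0)
        x_max = min(self.x_max, w - 1)
        y_max = min(self.y_max, h - 1)
        if x_min > x_max or y_min > y_max:
            raise ValueError(
                f"boundary box {self} lies entirely outside the {w}x{h} frame "
                "(seed position too close to the frame edge)"
            )
        return BoundaryBox(x_min, x_max, y_min, y_max)

    def dilate(self, margin: int) -> "BoundaryBox":
        return BoundaryBox(
            self.x_min - margin, self.x_max + margin, self.y_min - margin, self.y_max + margin
        )

    def contains(self, x: int, y: int) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


@dataclass(frozen=True)
class ScanResult:
    """Winning pixel of a scanning-circle search and its score."""

    position: tuple[int, int]
    score: float


def disc_radius(diameter: float) -> float:
    return diameter / 2.0


def disc_offsets(diameter: float) -> np.ndarray:
    """(dy, dx) integer offsets of all pixels within a disc of ``diameter``.

    Membership: Euclidean distance of the pixel centre from the disc centre
    ``<= diameter / 2``.  Offsets are returned in row-major order.
    """
    if diameter < 1:
        raise ValueError("diameter must be >= 1 pixel")
    r = disc_radius(diameter)
    reach = int(np.floor(r))
    dy, dx = np.mgrid[-reach : reach + 1, -reach : reach + 1]
    inside = dy * dy + dx * dx <= r * r
    return np.column_stack([dy[inside], dx[inside]])


def disc_mask(diameter: float) -> np.ndarray:
    """Boolean (2*floor(d/2)+1)-square mask of the disc footprint."""
    r = disc_radius(diameter)
    reach = int(np.floor(r))
    dy, dx = np.mgrid[-reach : reach + 1, -reach : reach + 1]
    return dy * dy + dx * dx <= r * r


def disc_variance(frame: np.ndarray, center: tuple[int, int], diameter: float) -> float:
    """Population variance of intensities in the disc centred at ``center``.

    ``center`` is ``(x, y)`` in pixels.  Disc pixels outside the frame are
    excluded.  Uses ``E[v^2] - E[v]^2`` so that the per-pixel value agrees
    exactly with the convolution-based field on integer-valued frames.
    """
    frame = np.asarray(frame)
    h, w = frame.shape
    x, y = center
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"disc centre ({x}, {y}) lies outside the {w}x{h} frame")
    offs = disc_offsets(diameter)
    yy = offs[:, 0] + y
    xx = offs[:, 1] + x
    keep = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
    vals = frame[yy[keep], xx[keep]].astype(np.float64)
    n = vals.size
    s = vals.sum()
    ss = (vals * vals).sum()
    return float(ss / n - (s / n) ** 2)


def focus_region(
    box: BoundaryBox, dsc: int, spec: GranularitySpec, frame_shape: tuple[int, int]
) -> BoundaryBox:
    """The window over which the granularity field must be computed.

    The search evaluates scanning circles centred on every box pixel, and
    each circle reads granularity values up to its radius away; the region is
    therefore the box dilated by the scanning-circle radius, clipped to the
    frame.  (The granularity-disc radius is handled inside the field
    computation itself.)
    """
    margin = int(np.floor(disc_radius(dsc)))
    return box.dilate(margin).clip(frame_shape)


@dataclass(frozen=True)
class GranularityField:
    """Granularity values over a rectangular window of the frame.

    ``values[j, i]`` is the variance at frame pixel
    ``(x0 + i, y0 + j)``; pixels outside the window were not computed.
    """

    values: np.ndarray
    x0: int
    y0: int
    frame_shape: tuple[int, int]

    def value_at(self, x: int, y: int) -> float:
        j, i = y - self.y0, x - self.x0
        if not (0 <= j < self.values.shape[0] and 0 <= i < self.values.shape[1]):
            raise ValueError(f"pixel ({x}, {y}) outside the computed field window")
        return float(self.values[j, i])


def granularity_field(
    frame: np.ndarray, region: BoundaryBox, spec: GranularitySpec
) -> GranularityField:
    """Per-pixel disc variance over ``region``.

    The value at each region pixel equals :func:`disc_variance` at that
    pixel.  Computed with disc-kernel convolutions on a crop of the frame
    that extends one granularity-disc radius beyond the region (clipped to
    the frame), so edge handling matches the direct definition.
    """
    frame = np.asarray(frame)
    region = region.clip(frame.shape)
    gr = int(np.floor(disc_radius(spec.gc_diameter)))
    crop_box = region.dilate(gr).clip(frame.shape)
    crop = frame[crop_box.y_min : crop_box.y_max + 1, crop_box.x_min : crop_box.x_max + 1]
    crop = crop.astype(np.float64)

    kernel = disc_mask(spec.gc_diameter).astype(np.float64)
    # out-of-crop pixels contribute zero weight: they are out-of-frame for
    # every region pixel, which is exactly the clipping contract
    count = ndimage.convolve(np.ones_like(crop), kernel, mode="constant", cval=0.0)
    s = ndimage.convolve(crop, kernel, mode="constant", cval=0.0)
    ss = ndimage.convolve(crop * crop, kernel, mode="constant", cval=0.0)
    var = ss / count - (s / count) ** 2
    np.maximum(var, 0.0, out=var)

    j0 = region.y_min - crop_box.y_min
    i0 = region.x_min - crop_box.x_min
    values = var[j0 : j0 + region.height, i0 : i0 + region.width]
    return GranularityField(np.ascontiguousarray(values), region.x_min, region.y_min, frame.shape)


def circle_mean_score(field: GranularityField, center: tuple[int, int], dsc: int) -> float:
    """Mean granularity within the scanning circle centred at ``center``.

    Disc pixels outside the frame are excluded; all in-frame disc pixels must
    lie inside the computed field window.
    """
    x, y = center
    h, w = field.frame_shape
    offs = disc_offsets(dsc)
    yy = offs[:, 0] + y
    xx = offs[:, 1] + x
    keep = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
    if not keep.any():
        raise ValueError(f"scanning circle at ({x}, {y}) has no pixel inside the frame")
    vals = [field.value_at(int(xi), int(yi)) for xi, yi in zip(xx[keep], yy[keep])]
    return float(np.mean(vals))


def scan_minimum(
    frame: np.ndarray, box: BoundaryBox, dsc: int, spec: GranularitySpec
) -> ScanResult:
    """Exhaustive scanning-circle search over every pixel of ``box``.

    Returns the box pixel whose scanning-circle mean granularity is minimal;
    ties are broken by the first minimum in row-major order of the box.
    """
    frame = np.asarray(frame)
    box = box.clip(frame.shape)
    region = focus_region(box, dsc, spec, frame.shape)
    field = granularity_field(frame, region, spec)

    # score every box pixel by gathering its disc from the field; pixels
    # outside the field window are outside the frame (the region was dilated
    # by the scanning radius), which realises frame-edge clipping
    offs = disc_offsets(dsc)
    ys = np.arange(box.y_min, box.y_max + 1)
    xs = np.arange(box.x_min, box.x_max + 1)
    cy, cx = np.meshgrid(ys, xs, indexing="ij")
    rows = cy.reshape(-1, 1) + offs[:, 0] - field.y0
    cols = cx.reshape(-1, 1) + offs[:, 1] - field.x0
    fh, fw = field.values.shape
    valid = (rows >= 0) & (rows < fh) & (cols >= 0) & (cols < fw)
    vals = field.values[np.clip(rows, 0, fh - 1), np.clip(cols, 0, fw - 1)]
    counts = valid.sum(axis=1)
    totals = np.where(valid, vals, 0.0).sum(axis=1)
    box_scores = (totals / counts).reshape(box.height, box.width)

    flat = int(np.argmin(box_scores))  # first minimum in row-major order
    j, i = divmod(flat, box.width)
    return ScanResult(
        position=(box.x_min + i, box.y_min + j), score=float(box_scores[j, i])
    )
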