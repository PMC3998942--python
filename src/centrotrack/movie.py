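"""In-memory movie container and embryo geometry.

A movie is an ordered stack of grayscale frames plus the physical metadata
needed to convert pixel tracks into micrometres and seconds.  Frames follow
raster conventions: origin at the top-left corner, ``x`` increasing rightward
(anterior to posterior for a correctly oriented embryo), ``y`` increasing
downward, 0-based integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Movie", "EmbryoGeometry"]


@dataclass
class Movie:
    """Ordered grayscale frame stack with physical metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Grayscale intensities, any integer or float dtype, finite and
        non-negative.
    resolution : float
        Pixel resolution in µm/pixel.
    frame_interval : float
        Time between consecutive frames in seconds.
    """

    frames: np.ndarray
    resolution: float = 0.129
    frame_interval: float = 0.5

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n_frames, height, width) stack, got shape {self.frames.shape}"
            )
        if self.resolution <= 0:
            raise ValueError("resolution must be positive (µm/pixel)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (seconds)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def frame(self, index: int) -> np.ndarray:
        return self.frames[index]


@dataclass
class EmbryoGeometry:
    """Size and placement of the embryo within the frame.

    The orientation contract is anterior at left, long (anterior-posterior)
    axis horizontal.  ``embryo_height`` is the transverse extent in pixels and
    is the length scale from which all engine window sizes are derived.
    """

    embryo_height: float
    embryo_length: float | None = None
    resolution: float = 0.129
    #: x pixel of the anterior pole (used for AP normalization; optional)
    x_anterior: float | None = None
    #: x pixel of the posterior pole
    x_posterior: float | None = None
    #: y pixel of the transverse midline
    y_center: float | None = None

    def __post_init__(self) -> None:
        if self.embryo_height <= 0:
            raise ValueError("embryo_height must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.embryo_length is not None and self.embryo_length <= 0:
            raise ValueError("embryo_length must be positive when given")
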