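"""Synthetic DIC-like embryo movies with known centrosome trajectories.

The simulator emulates the image features the tracker consumes, not DIC
optics: an elliptical embryo filled with dynamic high-variance speckle
(yolk-granule texture, regenerated every frame), two smooth low-variance
circular centrosome regions, and optional smooth nuclei discs, defocus
events and reduced contrast.  The default parameters mirror the standard
acquisition conditions: 0.129 µm/pixel, 2 frames/s, an embryo about
30 µm (232 px) high, centrosome diameter about 12% of the embryo height.

Trajectories follow the stereotypic first mitosis of the nematode zygote:
the posterior spindle pole is displaced toward the posterior along a smooth
sigmoidal ramp and oscillates transversely during anaphase; the anterior
pole shows a smaller anteriorward drift and smaller antiphase oscillations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .engine import CentrosomeTrack, SeedPair, default_params
from .movie import EmbryoGeometry, Movie

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_movie",
    "default_benchmark_suite",
    "degrade",
]


@dataclass(frozen=True)
class DefocusEvent:
    """Frames during which a centrosome drops out of the focal plane.

    ``strength`` is the blend weight of cytoplasm-like speckle painted over
    the smooth disc (1 = disc fully replaced by texture).
    """

    role: str
    frame_start: int
    frame_end: int
    strength: float = 0.9


@dataclass(frozen=True)
class NucleusSpec:
    """Smooth low-variance confounder disc (e.g. a reforming nucleus)."""

    x: float
    y: float
    diameter: float
    frame_start: int = 0
    frame_end: int | None = None


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a simulated movie.

    Identical spec + seed produce bit-identical movies.  Lengths are pixels
    unless noted; oscillation amplitudes are µm (converted through
    ``resolution``), periods are seconds.
    """

    frame_shape: tuple[int, int] = (260, 420)  # (height, width)
    embryo_center: tuple[float, float] = (210.0, 130.0)  # (x, y)
    embryo_semi_axes: tuple[float, float] = (195.0, 116.0)  # (AP, transverse)
    resolution: float = 0.129
    frame_interval: float = 0.5
    n_frames: int = 80

    centrosome_diameter: float = 28.0
    #: parabolic brightness profile of the disc: centre value and edge lift
    disc_base_intensity: float = 118.0
    disc_edge_lift: float = 10.0
    #: the smooth (texture-free) core ends at core_fraction * radius and the
    #: cytoplasm texture ramps back to full strength at outer_fraction *
    #: radius — DIC centrosomes fade into the cytoplasm rather than ending
    #: at a hard rim, and the soft edge is what makes the variance minimum
    #: unique for scanning circles near the centrosome size
    disc_core_fraction: float = 0.85
    disc_outer_fraction: float = 1.15

    cytoplasm_mean: float = 128.0
    cytoplasm_sd: float = 30.0
    texture_grain_px: float = 1.2
    background_intensity: float = 40.0

    #: posterior pole: AP drift (px, positive = posterior/right) on a
    #: logistic ramp, plus transverse sinusoid with a logistic onset envelope
    posterior_ap_start: float = 35.0  # px right of embryo centre
    posterior_ap_drift: float = 45.0
    anterior_ap_start: float = -55.0  # px left of embryo centre
    anterior_ap_drift: float = -15.0
    drift_midpoint_frame: float | None = None  # default n_frames / 2
    drift_tau_frames: float = 8.0

    posterior_osc_amp_um: float = 2.0
    anterior_osc_amp_um: float = 0.8
    osc_period_s: float = 30.0

    #: (n_frames, strength): the anterior disc loses contrast over the last
    #: n frames (late-mitosis degradation), the posterior over the first n
    #: frames (the pole is less distinct before it fully expands) — the
    #: asymmetries behind the forward/backward direction preferences
    anterior_fade: tuple[int, float] = (0, 0.0)
    posterior_fade: tuple[int, float] = (0, 0.0)

    nuclei: tuple[NucleusSpec, ...] = ()
    defocus: tuple[DefocusEvent, ...] = ()
    contrast_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0 < self.contrast_factor <= 1:
            raise ValueError("contrast_factor must lie in (0, 1]")
        for ev in self.defocus:
            if ev.frame_start > ev.frame_end or ev.frame_start < 0 or ev.frame_end >= self.n_frames:
                raise ValueError(f"invalid defocus range {ev}")

    @property
    def embryo_height(self) -> float:
        return 2.0 * self.embryo_semi_axes[1]

    @property
    def geometry(self) -> EmbryoGeometry:
        cx, cy = self.embryo_center
        a, b = self.embryo_semi_axes
        return EmbryoGeometry(
            embryo_height=self.embryo_height,
            embryo_length=2.0 * a,
            resolution=self.resolution,
            x_anterior=cx - a,
            x_posterior=cx + a,
            y_center=cy,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Rasterized per-frame centrosome positions of a simulated movie."""

    frame_indices: np.ndarray
    anterior: np.ndarray  # (N, 2) int (x, y)
    posterior: np.ndarray

    def positions(self, role: str) -> np.ndarray:
        if role == "anterior":
            return self.anterior
        if role == "posterior":
            return self.posterior
        raise ValueError(f"unknown role {role!r}")

    def to_track(self, role: str) -> CentrosomeTrack:
        pos = self.positions(role)
        entries = tuple(
            (int(f), int(x), int(y)) for f, (x, y) in zip(self.frame_indices, pos)
        )
        return CentrosomeTrack(
            role=role, entries=entries, direction="forward", params=default_params(role)
        )

    def seed_pair(self, role: str) -> SeedPair:
        pos = self.positions(role)
        return SeedPair(
            first_frame_position=(int(pos[0, 0]), int(pos[0, 1])),
            last_frame_position=(int(pos[-1, 0]), int(pos[-1, 1])),
        )


def _logistic(s: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-s))


def trajectories(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """Analytic (float) centrosome trajectories, (n_frames, 2) arrays of (x, y)."""
    cx, cy = spec.embryo_center
    t = np.arange(spec.n_frames, dtype=float)
    mid = spec.drift_midpoint_frame if spec.drift_midpoint_frame is not None else spec.n_frames / 2.0
    ramp = _logistic((t - mid) / spec.drift_tau_frames)
    phase = 2.0 * math.pi * (t * spec.frame_interval) / spec.osc_period_s
    envelope = ramp  # oscillations build as the spindle displaces

    out = {}
    for role, ap_start, ap_drift, amp_um, sign in (
        ("anterior", spec.anterior_ap_start, spec.anterior_ap_drift, spec.anterior_osc_amp_um, -1.0),
        ("posterior", spec.posterior_ap_start, spec.posterior_ap_drift, spec.posterior_osc_amp_um, 1.0),
    ):
        amp_px = amp_um / spec.resolution
        x = cx + ap_start + ap_drift * ramp
        y = cy + sign * amp_px * np.sin(phase) * envelope
        out[role] = np.column_stack([x, y])
    return out


def _check_inside_embryo(spec: SyntheticSpec, traj: dict[str, np.ndarray]) -> None:
    cx, cy = spec.embryo_center
    a, b = spec.embryo_semi_axes
    r = spec.disc_outer_fraction * spec.centrosome_diameter / 2.0
    for role, xy in traj.items():
        u = (xy[:, 0] - cx) / (a - r)
        v = (xy[:, 1] - cy) / (b - r)
        if np.any(u * u + v * v > 1.0):
            bad = int(np.argmax(u * u + v * v))
            raise ValueError(
                f"{role} trajectory leaves the embryo at frame {bad}; "
                "reduce drift/oscillation amplitudes or enlarge the embryo"
            )


def _speckle(rng: np.random.Generator, shape: tuple[int, int], sd: float, grain: float) -> np.ndarray:
    """Zero-mean correlated noise with the requested standard deviation."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, grain)
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _paint_disc(
    frame: np.ndarray, x: float, y: float, diameter: float,
    base: float, edge_lift: float, texture_mean: float,
    core_fraction: float = 0.85, outer_fraction: float = 1.15, blend: float = 1.0,
) -> None:
    """Paint a smooth low-variance region into a textured frame.

    The mean brightness follows a shallow parabolic profile; the existing
    texture fluctuations are suppressed completely inside the core radius
    and ramp back to full strength at the outer radius, so the local
    variance rises monotonically from the centre into the cytoplasm.
    ``blend`` < 1 (defocus) mixes the painted region back toward the
    underlying texture.
    """
    h, w = frame.shape
    r_outer = outer_fraction * diameter / 2.0
    r_core = core_fraction * diameter / 2.0
    y0, y1 = max(0, int(y - r_outer) - 1), min(h, int(y + r_outer) + 2)
    x0, x1 = max(0, int(x - r_outer) - 1), min(w, int(x + r_outer) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((xx - x) ** 2 + (yy - y) ** 2)
    mask = d <= r_outer
    atten = _smoothstep((d - r_core) / max(r_outer - r_core, 1e-9))
    profile = base + edge_lift * (d / r_outer) ** 2
    sub = frame[y0:y1, x0:x1]
    painted = profile + atten * (sub - texture_mean)
    sub[mask] = blend * painted[mask] + (1.0 - blend) * sub[mask]


def generate_movie(spec: SyntheticSpec) -> tuple[Movie, GroundTruth]:
    """Render a movie from ``spec`` and return it with its ground truth.

    Each frame is background + elliptical embryo filled with per-frame
    regenerated speckle + smooth centrosome discs at the trajectory
    positions + optional nuclei and degradations, quantized to 8 bit.
    """
    traj = trajectories(spec)
    _check_inside_embryo(spec, traj)

    h, w = spec.frame_shape
    cx, cy = spec.embryo_center
    a, b = spec.embryo_semi_axes
    yy, xx = np.mgrid[0:h, 0:w]
    embryo_mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0

    rng = np.random.default_rng(spec.seed)
    frames = np.empty((spec.n_frames, h, w), dtype=np.uint8)
    for t in range(spec.n_frames):
        frame = np.full((h, w), spec.background_intensity, dtype=np.float64)
        # cytoplasm texture is regenerated every frame: granularity is
        # dynamic, so frame-to-frame matching cannot rely on a static pattern
        texture = spec.cytoplasm_mean + _speckle(rng, (h, w), spec.cytoplasm_sd, spec.texture_grain_px)
        frame[embryo_mask] = texture[embryo_mask]

        for nuc in spec.nuclei:
            end = nuc.frame_end if nuc.frame_end is not None else spec.n_frames - 1
            if nuc.frame_start <= t <= end:
                _paint_disc(frame, nuc.x, nuc.y, nuc.diameter,
                            spec.disc_base_intensity + 8.0, spec.disc_edge_lift,
                            spec.cytoplasm_mean,
                            spec.disc_core_fraction, spec.disc_outer_fraction)

        for role in ("anterior", "posterior"):
            x, y = traj[role][t]
            blend = 1.0
            n_fade, strength = spec.anterior_fade if role == "anterior" else spec.posterior_fade
            if n_fade > 0:
                in_fade = t >= spec.n_frames - n_fade if role == "anterior" else t < n_fade
                if in_fade:
                    blend = 1.0 - strength
            for ev in spec.defocus:
                if ev.role == role and ev.frame_start <= t <= ev.frame_end:
                    blend = min(blend, 1.0 - ev.strength)
            _paint_disc(frame, x, y, spec.centrosome_diameter,
                        spec.disc_base_intensity, spec.disc_edge_lift,
                        spec.cytoplasm_mean,
                        spec.disc_core_fraction, spec.disc_outer_fraction, blend=blend)

        if spec.contrast_factor < 1.0:
            frame = spec.cytoplasm_mean + spec.contrast_factor * (frame - spec.cytoplasm_mean)
        frames[t] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)

    idx = np.arange(spec.n_frames)
    truth = GroundTruth(
        frame_indices=idx,
        anterior=np.rint(traj["anterior"]).astype(int),
        posterior=np.rint(traj["posterior"]).astype(int),
    )
    movie = Movie(frames, resolution=spec.resolution, frame_interval=spec.frame_interval)
    return movie, truth


#: cyclic variations applied by the default benchmark suite
_OSC_AMPS_UM = (1.0, 1.5, 2.0, 2.5, 3.0)
_DRIFTS_PX = (35.0, 45.0, 55.0)
_DIAMETERS_PX = (24.0, 28.0, 32.0)


def suite_spec(index: int, base_seed: int = 0, **overrides) -> SyntheticSpec:
    """Deterministic spec of movie ``index`` of the benchmark suite.

    Oscillation amplitude, posterior drift and centrosome size cycle through
    realistic ranges; every 10th movie starting at 6 carries a short
    (4-frame, i.e. recoverable) posterior defocus event, every 10th starting
    at 8 is acquired at reduced contrast.  Seeds derive reproducibly from
    ``base_seed``.
    """
    kw: dict = dict(
        posterior_osc_amp_um=_OSC_AMPS_UM[index % len(_OSC_AMPS_UM)],
        anterior_osc_amp_um=0.4 * _OSC_AMPS_UM[index % len(_OSC_AMPS_UM)],
        posterior_ap_drift=_DRIFTS_PX[index % len(_DRIFTS_PX)],
        centrosome_diameter=_DIAMETERS_PX[index % len(_DIAMETERS_PX)],
        seed=(base_seed * 1_000_003 + index) % (2**31 - 1),
    )
    if index % 2 == 0:
        kw["anterior_fade"] = (5, 0.6)
        kw["posterior_fade"] = (5, 0.6)
    if index % 10 == 6:
        mid = overrides.get("n_frames", 80) // 2
        kw["defocus"] = (DefocusEvent("posterior", mid, mid + 3),)
    if index % 10 == 8:
        kw["contrast_factor"] = 0.65
    kw.update(overrides)
    return SyntheticSpec(**kw)


def failure_demo_spec(seed: int = 13) -> SyntheticSpec:
    """A movie built to defeat the tracker the way real movies do.

    The posterior centrosome leaves the focal plane for 29 consecutive
    frames (far beyond the ~5-frame disappearance the engine tolerates)
    while a smooth nucleus sits near its path; the search locks onto the
    nucleus and never returns, producing a grossly aberrant trajectory
    (RMSD above the 3 µm outlier threshold).
    """
    return SyntheticSpec(
        n_frames=80,
        seed=seed,
        posterior_osc_amp_um=2.5,
        defocus=(DefocusEvent("posterior", 20, 48, strength=1.0),),
        nuclei=(NucleusSpec(264.0, 94.0, 28.0),),
    )


def default_benchmark_suite(
    n_movies: int, base_seed: int = 0, **overrides
) -> list[tuple[Movie, GroundTruth]]:
    """Deterministic family of simulated movies spanning varied dynamics.

    Keyword overrides are applied to every spec (e.g. ``n_frames=40`` for a
    faster suite, or ``centrosome_diameter=28.0`` for a homogeneous one).
    """
    if n_movies < 1:
        raise ValueError("n_movies must be >= 1")
    return [generate_movie(suite_spec(i, base_seed, **overrides)) for i in range(n_movies)]


def degrade(
    movie: Movie,
    contrast_factor: float = 1.0,
    defocus_ranges: Sequence[tuple[int, int]] = (),
    truth: GroundTruth | None = None,
    role: str = "posterior",
    disc_diameter: float = 28.0,
    strength: float = 0.9,
    seed: int = 0,
) -> Movie:
    """Degrade an existing movie: compress contrast and/or defocus a disc.

    Contrast compression pulls every intensity toward the movie mean by
    ``contrast_factor``.  During each ``(start, end)`` defocus range the
    smooth disc of ``role`` (located through ``truth``) is blended with
    cytoplasm-like speckle, erasing the variance gap the tracker relies on.
    """
    if not 0 < contrast_factor <= 1:
        raise ValueError("contrast_factor must lie in (0, 1]")
    for start, end in defocus_ranges:
        if start > end or start < 0 or end >= movie.n_frames:
            raise ValueError(f"invalid defocus range ({start}, {end})")
    if defocus_ranges and truth is None:
        raise ValueError("defocus ranges require the ground truth to locate the disc")
    if contrast_factor == 1.0 and not defocus_ranges:
        return movie

    frames = movie.frames.astype(np.float64).copy()
    rng = np.random.default_rng(seed)
    if defocus_ranges:
        pos = truth.positions(role)
        inside = movie.frames > 60  # embryo pixels (background is darker)
        mean = float(frames[inside].mean())
        sd = float(frames[inside].std())
        for start, end in defocus_ranges:
            for t in range(start, end + 1):
                x, y = pos[t]
                texture = mean + _speckle(rng, frames[t].shape, sd, 1.2)
                _paint_patch_from(frames[t], texture, float(x), float(y), disc_diameter, strength)

    if contrast_factor < 1.0:
        mean = frames.mean()
        frames = mean + contrast_factor * (frames - mean)

    out = np.clip(np.rint(frames), 0, 255).astype(movie.frames.dtype)
    return Movie(out, resolution=movie.resolution, frame_interval=movie.frame_interval)


def _paint_patch_from(
    frame: np.ndarray, source: np.ndarray, x: float, y: float, diameter: float, blend: float
) -> None:
    h, w = frame.shape
    r = diameter / 2.0
    y0, y1 = max(0, int(y - r) - 1), min(h, int(y + r) + 2)
    x0, x1 = max(0, int(x - r) - 1), min(w, int(x + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - x) ** 2 + (yy - y) ** 2 <= r * r
    sub = frame[y0:y1, x0:x1]
    src = source[y0:y1, x0:x1]
    sub[mask] = (1.0 - blend) * sub[mask] + blend * src[mask]
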