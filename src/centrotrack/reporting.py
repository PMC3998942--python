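"""Movie and report file I/O, per-movie configuration and batch running.

Movies come in as multi-page grayscale TIFF stacks (or a directory of
numbered single-page TIFFs).  Tracking results go out as tab-separated
report files with a ``#``-prefixed key=value header, one row per (frame,
role), positions both in pixels and µm plus normalized coordinates:
AP% runs 0 (anterior pole) to 100 (posterior pole); transverse% is 0 at the
cell midline and +50 at the upper edge (y grows downward, so positive is
up).  Overlay movies burn per-role markers into the frames; MP4 is used when
an encoder is available and a marker-burned TIFF stack otherwise.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .engine import (
    CentrosomeTrack,
    SeedPair,
    TrackingParams,
    default_params,
    scale_params,
    track_pair,
)
from .movie import EmbryoGeometry, Movie

__all__ = [
    "MovieConfig",
    "read_movie",
    "write_movie",
    "load_config",
    "normalize_position",
    "write_report",
    "read_report",
    "write_overlay_movie",
    "run_batch",
]

logger = logging.getLogger(__name__)

#: pixel resolutions (µm/px) over which the engine scaling is validated
VALIDATED_RESOLUTION_RANGE = (0.0645, 0.258)

REPORT_COLUMNS = [
    "movie_id", "role", "frame", "time_s",
    "x_px", "y_px", "x_um", "y_um", "ap_percent", "transverse_percent",
]


@dataclass
class MovieConfig:
    """Everything needed to track one movie without user interaction."""

    path: str
    resolution: float
    frame_interval: float
    embryo_height: float
    x_anterior: float
    x_posterior: float
    y_center: float
    seeds: dict[str, SeedPair]
    start_frame: int = 0
    end_frame: int | None = None
    embryo_length: float | None = None
    anaphase_onset_frame: int | None = None
    params: dict[str, TrackingParams] = field(default_factory=dict)
    movie_id: str | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0 or self.frame_interval <= 0:
            raise ValueError("resolution and frame_interval must be positive")
        lo, hi = VALIDATED_RESOLUTION_RANGE
        if not lo <= self.resolution <= hi:
            warnings.warn(
                f"resolution {self.resolution} µm/px is outside the validated "
                f"range [{lo}, {hi}]; tracking proceeds but parameters were "
                "not optimized there",
                stacklevel=2,
            )
        if self.x_posterior == self.x_anterior:
            raise ValueError("degenerate AP extent: x_anterior == x_posterior")
        if self.embryo_height <= 0:
            raise ValueError("embryo_height must be positive")
        if self.movie_id is None:
            self.movie_id = Path(self.path).stem

    @property
    def geometry(self) -> EmbryoGeometry:
        return EmbryoGeometry(
            embryo_height=self.embryo_height,
            embryo_length=self.embryo_length,
            resolution=self.resolution,
            x_anterior=self.x_anterior,
            x_posterior=self.x_posterior,
            y_center=self.y_center,
        )

    def frame_range(self, n_frames: int) -> tuple[int, int]:
        end = self.end_frame if self.end_frame is not None else n_frames - 1
        if not 0 <= self.start_frame < end < n_frames:
            raise ValueError(
                f"frame range ({self.start_frame}, {end}) invalid for a movie "
                f"of {n_frames} frames"
            )
        return (self.start_frame, end)


def _numeric_key(path: Path) -> tuple:
    nums = re.findall(r"\d+", path.stem)
    return (int(nums[-1]) if nums else 0, path.name)


def read_movie(path: str | Path, resolution: float = 0.129, frame_interval: float = 0.5) -> Movie:
    """Load a multi-page grayscale TIFF (or a directory of numbered TIFFs)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            [p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")],
            key=_numeric_key,
        )
        if not files:
            raise ValueError(f"no TIFF files in directory {path}")
        pages = []
        for p in files:
            arr = tifffile.imread(p)
            if arr.ndim != 2:
                raise ValueError(f"frame {p.name} is not single-page grayscale (shape {arr.shape})")
            pages.append(arr)
        shapes = {a.shape for a in pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame dimensions across {path}: {sorted(shapes)}")
        stack = np.stack(pages)
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(
            f"{path} is not a grayscale stack (shape {stack.shape}); RGB input "
            "is rejected rather than silently converted"
        )
    return Movie(stack, resolution=resolution, frame_interval=frame_interval)


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write the stack as a multi-page grayscale TIFF (lossless)."""
    tifffile.imwrite(Path(path), movie.frames)


def _seed_pair_from(obj) -> SeedPair:
    return SeedPair(
        first_frame_position=tuple(int(v) for v in obj["first"]),
        last_frame_position=tuple(int(v) for v in obj["last"]),
    )


def load_config(path: str | Path) -> MovieConfig:
    """Read a per-movie YAML configuration file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    seeds = {role: _seed_pair_from(raw["seeds"][role]) for role in ("anterior", "posterior")}
    params = {}
    for role, overrides in (raw.get("params") or {}).items():
        params[role] = default_params(role, **overrides)
    movie_path = raw["path"]
    if not Path(movie_path).is_absolute():
        movie_path = str(path.parent / movie_path)
    return MovieConfig(
        path=movie_path,
        resolution=float(raw["resolution"]),
        frame_interval=float(raw["frame_interval"]),
        embryo_height=float(raw["embryo_height"]),
        embryo_length=float(raw["embryo_length"]) if raw.get("embryo_length") else None,
        x_anterior=float(raw["x_anterior"]),
        x_posterior=float(raw["x_posterior"]),
        y_center=float(raw["y_center"]),
        seeds=seeds,
        start_frame=int(raw.get("start_frame", 0)),
        end_frame=int(raw["end_frame"]) if raw.get("end_frame") is not None else None,
        anaphase_onset_frame=(
            int(raw["anaphase_onset_frame"]) if raw.get("anaphase_onset_frame") is not None else None
        ),
        params=params,
        movie_id=raw.get("movie_id"),
    )


def normalize_position(position: tuple[float, float], config: MovieConfig) -> tuple[float, float]:
    """(AP%, transverse%) of a pixel position.

    AP% = 100 (x - x_anterior) / (x_posterior - x_anterior);
    transverse% = 100 (y_center - y) / embryo_height, positive toward the
    upper edge of the cell (+50 at the top, -50 at the bottom).
    """
    x, y = position
    ap = 100.0 * (x - config.x_anterior) / (config.x_posterior - config.x_anterior)
    tv = 100.0 * (config.y_center - y) / config.embryo_height
    return (ap, tv)


def _report_header(config: MovieConfig, tracks: list[CentrosomeTrack]) -> list[str]:
    lines = [
        f"# software_version={__version__}",
        f"# movie_id={config.movie_id}",
        f"# resolution_um_per_px={config.resolution}",
        f"# frame_interval_s={config.frame_interval}",
        f"# embryo_height_px={config.embryo_height}",
        f"# x_anterior_px={config.x_anterior}",
        f"# x_posterior_px={config.x_posterior}",
        f"# y_center_px={config.y_center}",
        f"# anaphase_onset_frame={config.anaphase_onset_frame}",
    ]
    for track in tracks:
        p = track.params
        sizes = scale_params(p, config.geometry)
        lines.append(
            f"# params_{track.role}="
            f"hbb_rel:{p.hbb_rel},dsc_rel:{p.dsc_rel},direction:{p.direction},"
            f"framerate_multiplier:{p.framerate_multiplier},gc_fraction:{p.gc_fraction},"
            f"box_split:{p.box_split},hbb_px:{sizes.hbb},wbb_px:{sizes.wbb},"
            f"dsc_px:{sizes.dsc},gc_px:{sizes.gc}"
        )
    return lines


def tracks_to_table(tracks: list[CentrosomeTrack], config: MovieConfig) -> pd.DataFrame:
    """Per-(frame, role) report rows with physical and normalized coordinates."""
    t0 = config.anaphase_onset_frame or 0
    rows = []
    for track in tracks:
        for frame, x, y in track.entries:
            ap, tv = normalize_position((x, y), config)
            rows.append({
                "movie_id": config.movie_id,
                "role": track.role,
                "frame": frame,
                "time_s": (frame - t0) * config.frame_interval,
                "x_px": x,
                "y_px": y,
                "x_um": x * config.resolution,
                "y_um": y * config.resolution,
                "ap_percent": ap,
                "transverse_percent": tv,
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(tracks: list[CentrosomeTrack], config: MovieConfig, path: str | Path) -> None:
    """Tab-separated report: '#' key=value header, then one row per
    (frame, role).  Decimal separator is always '.'."""
    table = tracks_to_table(tracks, config)
    path = Path(path)
    with open(path, "w") as fh:
        for line in _report_header(config, tracks):
            fh.write(line + "\n")
        table.to_csv(fh, sep="\t", index=False)


def read_report(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Parse a report file back into (table, header metadata)."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t")
    return table, meta


_MARKER_INTENSITY = {"anterior": 255, "posterior": 0}
_MARKER_ARMS = {"anterior": 5, "posterior": 7}


def _burn_marker(frame: np.ndarray, x: int, y: int, role: str) -> None:
    h, w = frame.shape
    value = _MARKER_INTENSITY[role]
    arm = _MARKER_ARMS[role]
    for d in range(-arm, arm + 1):
        if 0 <= x + d < w:
            frame[y, x + d] = value
        if 0 <= y + d < h:
            frame[y + d, x] = value


def write_overlay_movie(movie: Movie, tracks: list[CentrosomeTrack], path: str | Path) -> Path:
    """Burn per-role markers into the frames and write a movie file.

    Anterior is a short white cross, posterior a longer black one.  An
    MP4/AVI container is used when an ffmpeg-backed encoder is importable;
    otherwise a marker-burned TIFF stack is written next to ``path`` with a
    warning (never a silent failure).  Returns the path actually written.
    """
    frame_by_index: dict[int, list[tuple[int, int, str]]] = {}
    for track in tracks:
        for frame, x, y in track.entries:
            frame_by_index.setdefault(frame, []).append((x, y, track.role))

    burned = []
    for frame, markers in sorted(frame_by_index.items()):
        img = movie.frame(frame).copy()
        if img.dtype != np.uint8:
            lo, hi = float(img.min()), float(img.max())
            img = ((img - lo) / max(hi - lo, 1) * 255).astype(np.uint8)
        for x, y, role in markers:
            _burn_marker(img, x, y, role)
        burned.append(img)
    stack = np.stack(burned)

    path = Path(path)
    if path.suffix.lower() in (".mp4", ".avi"):
        try:
            import imageio.v2 as iio

            writer = iio.get_writer(path, fps=max(1, int(round(1.0 / movie.frame_interval))))
            for img in stack:
                writer.append_data(img)
            writer.close()
            return path
        except Exception as exc:  # no encoder available
            fallback = path.with_suffix(".overlay.tif")
            warnings.warn(
                f"no movie encoder available ({exc}); writing marker-burned "
                f"TIFF stack to {fallback}",
                stacklevel=2,
            )
            path = fallback
    tifffile.imwrite(path, stack)
    return path


def plot_displacement(table: pd.DataFrame, path: str | Path) -> Path:
    """Plot normalized displacement curves from a report table.

    Top panel: anterior-posterior position (0% = anterior pole, 100% =
    posterior pole); bottom panel: transverse position (0% = cell midline,
    +50% = upper edge), both against time.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_ap, ax_tv) = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
    colors = {"anterior": "tab:cyan", "posterior": "tab:pink"}
    for role, sub in table.groupby("role"):
        sub = sub.sort_values("frame")
        ax_ap.plot(sub["time_s"], sub["ap_percent"], label=role, color=colors.get(role))
        ax_tv.plot(sub["time_s"], sub["transverse_percent"], color=colors.get(role))
    ax_ap.set_ylabel("AP position (%)")
    ax_ap.set_ylim(0, 100)
    ax_ap.legend(frameon=False)
    ax_tv.set_ylabel("transverse (%)")
    ax_tv.set_ylim(-50, 50)
    ax_tv.axhline(0.0, lw=0.5, color="gray")
    ax_tv.set_xlabel("time (s)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def track_one(config: MovieConfig, movie: Movie | None = None) -> list[CentrosomeTrack]:
    """Track both centrosomes of one configured movie."""
    if movie is None:
        movie = read_movie(config.path, config.resolution, config.frame_interval)
    anterior, posterior = track_pair(
        movie,
        config.seeds,
        config.geometry,
        params=config.params or None,
        frame_range=config.frame_range(movie.n_frames),
    )
    return [anterior, posterior]


def run_batch(
    configs: list[MovieConfig],
    out_dir: str | Path,
    references: dict[str, dict[str, CentrosomeTrack]] | None = None,
    write_overlays: bool = True,
) -> pd.DataFrame:
    """Track a list of configured movies sequentially.

    All configs are validated up front (an invalid one aborts the whole
    batch before any tracking, listing every offender); after that, a
    failure in one movie is recorded in the summary and does not stop the
    others.  When reference tracks are supplied, per-role RMSDs are added to
    the summary.  Returns the summary table (one row per config) which is
    also written to ``summary.tsv``.
    """
    from .evaluate import rmsd  # local import to avoid a cycle

    if not configs:
        raise ValueError("empty batch: no movie configurations given")
    problems = []
    for cfg in configs:
        if not Path(cfg.path).exists():
            problems.append(f"{cfg.movie_id}: movie file {cfg.path} not found")
    if problems:
        raise ValueError("invalid batch configuration:\n" + "\n".join(problems))

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cfg in configs:
        row: dict = {"movie_id": cfg.movie_id, "status": "ok", "error": ""}
        try:
            movie = read_movie(cfg.path, cfg.resolution, cfg.frame_interval)
            tracks = track_one(cfg, movie)
            write_report(tracks, cfg, out_dir / f"{cfg.movie_id}.report.tsv")
            if write_overlays:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    write_overlay_movie(movie, tracks, out_dir / f"{cfg.movie_id}.overlay.tif")
            if references and cfg.movie_id in references:
                for track in tracks:
                    ref = references[cfg.movie_id].get(track.role)
                    if ref is not None:
                        row[f"rmsd_{track.role}_um"] = rmsd(track, ref, cfg.resolution)
        except Exception as exc:
            logger.error("movie %s failed: %s", cfg.movie_id, exc)
            row["status"] = "failed"
            row["error"] = str(exc)
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    return summary
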