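"""Trajectory evaluation, parameter optimization and robustness experiments.

The quantitative yardstick throughout is the root-mean-square deviation
(RMSD) between a tracked trajectory and a reference trajectory over matched
frames, converted to µm through the pixel resolution:

    RMSD = r * sqrt( (1/N) * sum_i [ (x_i - x_i,ref)^2 + (y_i - y_i,ref)^2 ] )

Parameter fitting minimizes a scoring function SF = mean RMSD over a
training set of movies (optionally after skipping the k largest values,
which de-weights gross outliers), scanning a grid of relative boundary-box
heights and scanning-circle diameters in both tracking directions, with
hold-out validation on a disjoint test set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .engine import CentrosomeTrack, TrackingParams, default_params, track_centrosome
from .movie import EmbryoGeometry, Movie
from .simulate import GroundTruth

__all__ = [
    "rmsd",
    "rmsd_sd",
    "scoring_function",
    "cumulative_distribution",
    "flag_outliers",
    "holdout_split",
    "HoldoutSplit",
    "GridSpec",
    "ScanSurface",
    "grid_scan",
    "robustness_experiment",
    "OUTLIER_THRESHOLD_UM",
]

logger = logging.getLogger(__name__)

#: tracks deviating from the reference by more than this are gross failures
OUTLIER_THRESHOLD_UM = 3.0

#: coarse scan: 0.5..1.5 step 0.25 on both axes
COARSE_GRID = (tuple(np.arange(0.5, 1.5001, 0.25)), tuple(np.arange(0.5, 1.5001, 0.25)))
#: fine scan: step 0.125, dsc axis extended to 1.75
FINE_GRID = (tuple(np.arange(0.5, 1.5001, 0.125)), tuple(np.arange(0.5, 1.7501, 0.125)))


def _matched_positions(track: CentrosomeTrack, reference: CentrosomeTrack) -> tuple[np.ndarray, np.ndarray]:
    fi, fr = track.frame_indices, reference.frame_indices
    if fi.shape != fr.shape or np.any(fi != fr):
        raise ValueError(
            f"frame-index mismatch between track ({fi[0]}..{fi[-1]}, n={len(fi)}) "
            f"and reference ({fr[0]}..{fr[-1]}, n={len(fr)})"
        )
    return track.positions.astype(float), reference.positions.astype(float)


def rmsd(track: CentrosomeTrack, reference: CentrosomeTrack, resolution: float) -> float:
    """RMSD between two trajectories over matched frames, in µm."""
    p, q = _matched_positions(track, reference)
    d2 = np.sum((p - q) ** 2, axis=1)
    return float(resolution * np.sqrt(d2.mean()))


def rmsd_sd(values: np.ndarray | list[float]) -> float:
    """Sample standard deviation (n-1 denominator) of per-movie RMSDs."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("rmsd_sd requires at least 2 values")
    return float(values.std(ddof=1))


def scoring_function(rmsds: np.ndarray | list[float], skip_largest: int = 0) -> float:
    """Mean RMSD over a training set; optionally skip the k largest values.

    Skipping the largest values (the outlier-robust variant, typically the
    top 10%) asks for parameters that remain optimal once gross failures a
    user would discard are removed.
    """
    values = np.asarray(rmsds, dtype=float)
    if values.size == 0:
        raise ValueError("scoring_function requires at least one RMSD")
    if skip_largest < 0 or skip_largest >= values.size:
        raise ValueError("skip_largest must be in [0, n_movies)")
    if skip_largest:
        values = np.sort(values)[: values.size - skip_largest]
    return float(values.mean())


def cumulative_distribution(values: np.ndarray | list[float], bin_width: float = 0.1) -> np.ndarray:
    """Normalized cumulative distribution on a regular grid of bin edges.

    Returns an (n_edges, 2) array of (edge, fraction of values <= edge);
    edges run from 0 to the first multiple of ``bin_width`` covering the
    maximum, so the curve ends at 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cumulative_distribution requires at least one value")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_edges = int(np.ceil(values.max() / bin_width)) + 1
    edges = np.arange(n_edges + 1) * bin_width
    frac = np.array([(values <= e).mean() for e in edges])
    return np.column_stack([edges, frac])


def flag_outliers(rmsds: np.ndarray | list[float], threshold: float = OUTLIER_THRESHOLD_UM) -> np.ndarray:
    """Flag gross tracking failures: RMSD above ``threshold`` (µm)."""
    return np.asarray(rmsds, dtype=float) > threshold


@dataclass(frozen=True)
class HoldoutSplit:
    train_ids: tuple
    test_ids: tuple
    seed: int


def holdout_split(movie_ids, train_fraction: float = 2.0 / 3.0, seed: int = 0) -> HoldoutSplit:
    """Deterministic shuffled split into training and test sets.

    With 54 movies and the default 2/3 fraction this yields 36 training and
    18 test movies.
    """
    ids = list(movie_ids)
    if len(ids) < 3:
        raise ValueError("holdout_split requires at least 3 movies")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    train = tuple(ids[i] for i in sorted(order[:n_train]))
    test = tuple(ids[i] for i in sorted(order[n_train:]))
    return HoldoutSplit(train_ids=train, test_ids=test, seed=seed)


@dataclass(frozen=True)
class GridSpec:
    """Axes of a parameter scan (relative hbb and dsc values)."""

    hbb_values: tuple[float, ...] = COARSE_GRID[0]
    dsc_values: tuple[float, ...] = COARSE_GRID[1]

    def __post_init__(self) -> None:
        for axis in (self.hbb_values, self.dsc_values):
            if len(axis) == 0 or np.any(np.diff(axis) <= 0):
                raise ValueError("grid axes must be non-empty and strictly increasing")


@dataclass(frozen=True)
class ScanSurface:
    """Scoring-function values over a (hbb_rel, dsc_rel) grid."""

    hbb_values: tuple[float, ...]
    dsc_values: tuple[float, ...]
    sf: np.ndarray  # (n_hbb, n_dsc), µm
    rmsd_per_movie: np.ndarray  # (n_hbb, n_dsc, n_movies)
    direction: str
    role: str
    skip_largest: int

    @property
    def argmin(self) -> tuple[float, float]:
        """(hbb_rel, dsc_rel) minimizing the scoring function."""
        j, i = np.unravel_index(int(np.argmin(self.sf)), self.sf.shape)
        return (self.hbb_values[j], self.dsc_values[i])


def grid_scan(
    training_set: list[tuple[Movie, GroundTruth]],
    role: str,
    grid: GridSpec | None = None,
    directions: tuple[str, ...] = ("forward", "backward"),
    skip_largest: int = 0,
    geometry: EmbryoGeometry | None = None,
    geometries: list[EmbryoGeometry] | None = None,
) -> dict[str, ScanSurface]:
    """Scoring-function surface per direction over the parameter grid.

    For every (hbb_rel, dsc_rel, direction) combination, every training
    movie is tracked from its ground-truth seed and scored against its
    reference; a failed tracking contributes RMSD = +inf (failures dominate
    the mean unless trimmed away, as they should).
    """
    grid = grid or GridSpec()
    n = len(training_set)
    if n == 0:
        raise ValueError("training set is empty")
    if geometries is None:
        geometries = [geometry] * n

    surfaces: dict[str, ScanSurface] = {}
    for direction in directions:
        per_movie = np.full((len(grid.hbb_values), len(grid.dsc_values), n), np.inf)
        for (j, hbb_rel), (i, dsc_rel) in itertools.product(
            enumerate(grid.hbb_values), enumerate(grid.dsc_values)
        ):
            params = default_params(role, hbb_rel=hbb_rel, dsc_rel=dsc_rel, direction=direction)
            for k, (movie, truth) in enumerate(training_set):
                geom = geometries[k]
                seed_pair = truth.seed_pair(role)
                seed = (
                    seed_pair.first_frame_position
                    if direction == "forward"
                    else seed_pair.last_frame_position
                )
                try:
                    track = track_centrosome(movie, seed, params, geom)
                    per_movie[j, i, k] = rmsd(track, truth.to_track(role), movie.resolution)
                except (ValueError, RuntimeError) as exc:
                    logger.warning(
                        "movie %d failed at hbb=%.3f dsc=%.3f %s: %s",
                        k, hbb_rel, dsc_rel, direction, exc,
                    )
        finite = np.where(np.isfinite(per_movie), per_movie, np.inf)
        sf = np.empty(finite.shape[:2])
        for j, i in np.ndindex(sf.shape):
            sf[j, i] = scoring_function(finite[j, i], skip_largest=skip_largest)
        surfaces[direction] = ScanSurface(
            hbb_values=tuple(grid.hbb_values),
            dsc_values=tuple(grid.dsc_values),
            sf=sf,
            rmsd_per_movie=per_movie,
            direction=direction,
            role=role,
            skip_largest=skip_largest,
        )
    return surfaces


@dataclass(frozen=True)
class RobustnessResult:
    """Outcome of one perturbed-seed tracking run."""

    offset_px: tuple[int, int]
    offset_um: float
    global_rmsd_um: float
    #: 1-based step count (after tracking initiation) from which the
    #: perturbed track coincides with the reference for all later steps;
    #: +inf if it never catches up
    convergence_frame: float


def _visitation_order_positions(track: CentrosomeTrack) -> np.ndarray:
    pos = track.positions
    return pos if track.direction == "forward" else pos[::-1]


def convergence_frame(perturbed: CentrosomeTrack, reference: CentrosomeTrack) -> float:
    """First step (1-based, in visitation order) from which the two tracks
    coincide exactly until the end; +inf if they never do."""
    p = _visitation_order_positions(perturbed)
    q = _visitation_order_positions(reference)
    same = np.all(p == q, axis=1)
    if not same[-1]:
        return float("inf")
    diverged = np.nonzero(~same)[0]
    return 1.0 if diverged.size == 0 else float(diverged[-1] + 2)


def robustness_experiment(
    movie: Movie,
    truth: GroundTruth,
    role: str,
    params: TrackingParams | None = None,
    geometry: EmbryoGeometry | None = None,
    max_offset_um: float = 1.2,
    spacing_um: float = 0.129,
    stride: int = 1,
) -> list[RobustnessResult]:
    """Rerun tracking from seed positions perturbed on a regular grid.

    Offsets enumerate all (dx, dy) grid points (``spacing_um`` apart,
    converted to whole pixels) with Euclidean norm <= ``max_offset_um``;
    ``stride`` subsamples the grid (every ``stride``-th point per axis) for
    faster runs.  The reference is the run seeded at the unperturbed
    position.  Offsets that leave the frame are skipped with a log entry.
    """
    params = params or default_params(role)
    geometry = geometry or EmbryoGeometry(embryo_height=movie.height * 0.9, resolution=movie.resolution)
    seed_pair = truth.seed_pair(role)
    base = (
        seed_pair.first_frame_position
        if params.direction == "forward"
        else seed_pair.last_frame_position
    )
    reference = track_centrosome(movie, base, params, geometry)

    spacing_px = spacing_um / movie.resolution
    reach = int(np.floor(max_offset_um / spacing_um))
    results: list[RobustnessResult] = []
    for iy in range(-reach, reach + 1, stride):
        for ix in range(-reach, reach + 1, stride):
            off_um = spacing_um * float(np.hypot(ix, iy))
            if off_um > max_offset_um + 1e-9:
                continue
            dx = int(round(ix * spacing_px))
            dy = int(round(iy * spacing_px))
            seed = (base[0] + dx, base[1] + dy)
            if not (0 <= seed[0] < movie.width and 0 <= seed[1] < movie.height):
                logger.info("offset (%d, %d) px places the seed outside the frame; skipped", dx, dy)
                continue
            perturbed = track_centrosome(movie, seed, params, geometry)
            results.append(
                RobustnessResult(
                    offset_px=(dx, dy),
                    offset_um=off_um,
                    global_rmsd_um=rmsd(perturbed, reference, movie.resolution),
                    convergence_frame=convergence_frame(perturbed, reference),
                )
            )
    return results
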