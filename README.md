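# centrotrack

Automated tracking of the two mitotic-spindle poles (centrosomes) in DIC
movies of one-cell nematode embryos.

During the first mitosis of *C. elegans* and related nematodes, the spindle
is displaced toward the posterior and its poles oscillate transversely.
Quantifying these trajectories usually means clicking two points per frame
for hundreds of frames.  In DIC images the cytoplasm is packed with yolk
granules and therefore shows a high local variance of pixel intensities
("granularity"), while centrosomes appear as smooth, low-variance circular
regions.  `centrotrack` exploits this contrast: for each frame it projects
the previous centrosome position, places a small search box around it
(shifted toward the pole's expected direction of motion), and picks the
pixel whose *scanning circle* has the minimal mean granularity:

```
position_t = argmin_{p in box(position_{t-1})}  mean_{q in disc(p, dsc)} Var_gc(q)
```

where `Var_gc(q)` is the population variance of intensities in a small disc
(~1% of the embryo height) centred on `q`, the scanning-circle diameter
`dsc` is `dsc_rel × 12%` of the embryo height, and the box height `hbb` is
`hbb_rel × 4%` of the embryo height (width = half the height).  All sizes
scale with the embryo height, so movies with pixel resolutions from 0.0645
to 0.258 µm/px are handled without re-tuning.  The optimized defaults are
`(hbb_rel, dsc_rel) = (1.125, 1.250)` tracked forward for the anterior pole
and `(1.375, 1.125)` tracked backward for the posterior pole.

The package also provides:

* a synthetic DIC-movie simulator with exact ground-truth trajectories
  (elliptical embryo, dynamic speckle cytoplasm, smooth centrosome discs,
  optional nuclei, defocus events and contrast degradation);
* trajectory evaluation — RMSD in µm, outlier flagging (> 3 µm),
  cumulative RMSD distributions (0.1 µm bins);
* parameter optimization — scoring-function (mean RMSD) surfaces over
  `(hbb_rel, dsc_rel, direction)` grids with hold-out splitting and
  outlier-trimmed scoring;
* a perturbed-seed robustness experiment (offsets up to 1.2 µm on a
  0.129 µm grid);
* a batch-capable CLI with tab-separated report files and marker-burned
  overlay movies.

## Worked example

```python
from centrotrack import default_params, generate_movie, rmsd, track_centrosome
from centrotrack.simulate import SyntheticSpec

spec = SyntheticSpec(seed=42)           # 80 frames, 232 px embryo, 0.129 um/px
movie, truth = generate_movie(spec)

for role in ("anterior", "posterior"):
    params = default_params(role)       # anterior: forward; posterior: backward
    sp = truth.seed_pair(role)
    seed = sp.first_frame_position if params.direction == "forward" else sp.last_frame_position
    track = track_centrosome(movie, seed, params, spec.geometry)
    err = rmsd(track, truth.to_track(role), movie.resolution)
    print(f"{role:9s} dir={params.direction:8s} RMSD vs truth = {err:.3f} um")
```

prints

```
anterior  dir=forward  RMSD vs truth = 0.380 um
posterior dir=backward RMSD vs truth = 0.168 um
```

i.e. both poles are recovered to well under the ~0.6 µm precision of human
manual tracking (about 2% of the embryo height).

The same pipeline from the shell:

```sh
centrotrack simulate --seed 42 --out embryo.tif      # movie + ground truth
centrotrack track config.yaml --out-dir results/     # report + overlay
centrotrack optimize --role anterior --n-movies 12   # scoring-function scan
centrotrack robustness --role anterior --stride 2    # perturbed-seed study
```

`config.yaml` holds the movie path, pixel resolution, frame interval,
embryo geometry and the clicked seed positions on the first and last
analyzed frame (`centrotrack snapshot` prints a frame with a coordinate
grid to read them off).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

simulates three benchmark movies from scratch, perturbs each centrosome's
seed position on the stated offset grid (every 2nd point for speed),
re-tracks from every offset, and reports the worst-case number of frames
until the perturbed run coincides exactly with the unperturbed reference
tracking.
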