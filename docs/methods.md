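# Methods

## The tracking model

A centrosome in a DIC image is a smooth, roughly circular region whose
local intensity variance is far below that of the granule-filled cytoplasm.
The tracker treats detection as a constrained discrete search repeated
frame by frame:

1. **Projection.** The position found in the previous frame (the clicked
   seed on the first processed frame) is projected onto the current frame.
2. **Granularity.** The granularity at a pixel is the *population* variance
   of intensities in a disc of diameter `gc` centred there.  Discs contain
   every pixel whose centre lies within `diameter/2` (Euclidean) of the
   disc centre; discs and boxes are clipped to the frame and clipped discs
   use only in-frame pixels.  Population rather than sample variance is
   used because the value is a texture descriptor, not an estimate of a
   sampled population; the choice is fixed and pinned by tests.
3. **Boundary box.** A box of height `hbb` and width `wbb = hbb/2` is
   centred vertically on the projection.  Horizontally, a configurable
   fraction (default 2/3) of the box width is placed on the side of the
   pole's expected motion: anteriorward for the anterior pole and
   posteriorward for the posterior pole in forward time, reversed when
   tracking backward.  The exact split is a package design choice — the
   asymmetry reflects the poles' stereotyped drift, and 2/3 keeps a
   margin for counter-movements.
4. **Scan.** The scanning circle (diameter `dsc`) is centred on every box
   pixel; the pixel minimising the mean granularity inside the circle is
   the new position.  Ties break to the first minimum in row-major order
   of the box, making results implementation-independent.  The granularity
   field is computed once per frame over the box dilated by the scanning
   radius (a disc-kernel convolution with explicit edge counts), so the
   scan reads only exact values.

All sizes derive from the embryo height `H` (transverse extent in pixels):
`hbb = round(hbb_rel · 0.04 H · m)`, `wbb = round(hbb/2)`,
`dsc = roundodd(dsc_rel · 0.12 H)`, `gc = roundodd(0.01 H)`, with minima of
3 px (1 px for `wbb`) and `m ≥ 1` a frame-rate multiplier for slowly
acquired movies (≈3 at 0.2 frames/s versus the standard 2 frames/s).
Odd rounding gives discs a unique centre pixel.  Defaults
`(hbb_rel, dsc_rel, direction)` are (1.125, 1.250, forward) for the
anterior and (1.375, 1.125, backward) for the posterior pole.

Consequences worth knowing:

* per-frame displacement is bounded by the box, so a jump beyond
  `wbb`/`hbb` px per frame cannot be followed — this is a contract, not a
  bug, and is what makes long focal-plane dropouts fatal;
* the seed frame is itself re-scanned (the click only centres the first
  box), which is why small clicking errors are corrected — the basis of
  the perturbed-seed robustness experiment;
* there is no recovery logic: after a long dropout the engine keeps
  returning in-box minima, typically locking onto another smooth object
  (e.g. a nucleus), and the error is meant to be caught by the > 3 µm
  outlier flag.

## Evaluation and optimization

`RMSD = r · sqrt(mean_i[(x_i − x_i,ref)² + (y_i − y_i,ref)²])` over matched
frames, in µm (`r` = resolution in µm/px).  The spread over a movie set is
the sample standard deviation (n−1).  The scoring function for parameter
fitting is the mean RMSD over a training set; the trimmed variant drops
the k largest values (typically the top 10%) so that parameters remain
optimal once gross failures a user would discard are removed.  Failed
trackings enter a scan cell as +inf rather than being dropped — failures
should dominate a cell unless trimming explicitly removes them.  Grid
scans cover 0.5–1.5 (step 0.25) coarsely and step 0.125 finely with the
`dsc` axis extended to 1.75; hold-out splitting reserves 1/3 of movies for
validation.  Cumulative RMSD distributions use 0.1 µm bins.

The robustness experiment re-seeds tracking at every grid offset
(0.129 µm spacing) within 1.2 µm of the reference seed and reports the
global RMSD against the reference run plus the *convergence frame*: the
first tracking step (1-based, counted in visitation order from the start
of tracking) from which the perturbed trajectory coincides with the
reference exactly until the end.  Exact coincidence is well-defined
because positions are integer pixels and the engine is deterministic;
once two runs agree at one step they agree forever after.

## The synthetic world

The simulator produces what the algorithm consumes — variance structure —
not DIC optics.  Defaults mirror the standard acquisition conditions:
0.129 µm/px, 0.5 s frame interval, 8-bit frames of 420×260 px, an embryo
ellipse of 390×232 px (~50×30 µm), 80 frames, centrosome diameter 28 px
(12% of the embryo height).  Cytoplasm is per-frame regenerated smoothed
white noise (grain ≈ 1.2 px, SD 30 around mid-gray 128), so granularity is
dynamic and nothing can be matched against a static background.  A
centrosome is a disc with a shallow parabolic brightness profile whose
texture is fully suppressed inside 0.85× its radius and ramps back to full
strength at 1.15× (smoothstep).  The soft edge matters: with a hard rim,
any scanning circle larger than the disc sees a flat score plateau and the
minimum degenerates; with the soft edge the variance bowl is strict and
the minimum unique whenever `dsc` is within roughly ±15% of the disc
diameter — which is also why the grid scan can recover the matched
`dsc_rel` from tracking accuracy alone.

Trajectories follow the stereotyped first mitosis: the posterior pole's
AP position rides a logistic ramp (default 45 px ≈ 5.8 µm of posterior
displacement, midpoint mid-movie, time constant 8 frames) and oscillates
transversely (default 2 µm amplitude, 30 s period) under the same logistic
onset envelope; the anterior pole gets a smaller anteriorward drift
(−15 px) and antiphase oscillations at 40% amplitude.  Per-frame ground
truth steps stay within the default box reach, so the engine can in
principle follow every default movie.

The 20-movie benchmark suite cycles oscillation amplitudes 1–3 µm,
posterior drifts 35–55 px and centrosome diameters 24–32 px; every second
movie fades the anterior disc over its last 5 frames and the posterior
over its first 5 (contrast ×0.4) — emulating the late flattening of the
anterior region and the initially unexpanded posterior pole; every 10th
movie (index 6 mod 10) carries a short, recoverable 4-frame posterior
defocus, and every 10th (index 8 mod 10) is rendered at 0.65 contrast.
`failure_demo_spec` is the deliberate counter-example: a 29-frame
posterior dropout with a nucleus near the path, which reliably derails the
track beyond the 3 µm outlier threshold by the documented mechanism.

What a green synthetic test does *not* establish: performance on real DIC
shading (bas-relief asymmetry), on spindle-internal structure between the
poles, on drifting stages or rotating embryos, or on the granularity
changes of real mitotic stages.  The suite is a controlled world whose
signal-to-confounder geometry is chosen, not measured.

## Numerical choices and edge cases

* Integer pixel positions throughout; origin top-left, x rightward
  (anterior→posterior), y downward, 0-based.  Transverse normalization is
  therefore `+50%` at the *top* edge: `100 · (y_center − y) / H`.
* Rounding is "half away from zero" (`floor(x + 0.5)`), not banker's
  rounding, so window sizes are platform-stable.
* The variance field uses `E[v²] − E[v]²` with disc-kernel convolutions
  and explicit edge counts; on integer-valued frames this is exactly equal
  to the direct per-pixel definition (all intermediate sums are integers
  below 2^53), and tests pin both paths to brute-force enumeration.
* Frame-reversal symmetry (reversed movie + opposite direction + swapped
  seeds ⇒ exactly time-reversed track) holds structurally when the
  horizontal box split is symmetric (0.5); at the default 2/3 split the
  mirrored boxes can occasionally exclude the minimum, so exactness is
  only statistical there.
* Movies shorter than 2 frames, seeds outside the frame, boxes clipped to
  nothing, and scanning circles with no in-frame pixel all raise errors
  naming the offending quantity; a tracking failure inside a batch is
  recorded per movie without aborting the batch.
* The overlay writer falls back from MP4/AVI to a marker-burned TIFF stack
  with a warning when no encoder is installed.

## Limitations

The engine is exhaustive and integer-valued by design: no sub-pixel
localization, no FFT acceleration, no multi-particle tracking, no
automatic anaphase-onset detection.  Parameter defaults assume ~2 frames/s
acquisition; at lower frame rates the boundary box must be enlarged via
the frame-rate multiplier, which raises CPU cost quadratically in the box
area.  Embryos must be oriented anterior-left with the long axis
horizontal before analysis.
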