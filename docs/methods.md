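# Methods

`spherox` quantifies three phenomena in tumour-spheroid cultures exposed to
controlled, time-varying oxygen: reversible spheroid swelling under cycling
hypoxia, the single-cell swelling that drives it, and
oxygen-condition-dependent doxorubicin accumulation and penetration.  Because
no raw microscopy from such experiments is bundled, every analysis stage is
validated against a synthetic phantom generator whose ground truth is known
exactly.  This note records the models, the parameters that matter, the
numerical choices, and what the phantom does and does not emulate.

## Oxygen schedules

A schedule is an ordered list of constant-oxygen gas phases `(duration_min,
o2_pct)` repeated `repeat_count` times, e.g. `2 h 0% / 6 h 3% / 4 h 10% O2`.
Phases are left-closed, right-open, so any time inside the schedule maps to
exactly one oxygen level.  Oxygen is expressed as percent of 1 atm in
[0, 25]; 0% models severe hypoxia, ~3% typical tumour oxygenation, 10%
physiologic normoxia, 20% standard incubator ("in vitro normoxia").

## Swelling kinetics

The spheroid's linear scale factor s(t) relaxes first-order toward an
oxygen-dependent equilibrium:

    ds/dt = (s_eq(o2(t)) − s) / τ

Projected area then scales as s². The relaxation time defaults to
τ = 30 min so that a 2 h plateau reaches >98% of its equilibrium — chosen to
reproduce the observed sub-hour onset of swelling after a gas switch.  No
measured rate constant exists for this phenomenon; τ is the single most
uncertain phantom parameter, and phantom realism in the sub-hour regime is
correspondingly unvalidated.  The integrator applies the exact per-interval
exponential update, sub-stepping at phase boundaries, so traces are exact on
any sampling grid.

`calibrate_swelling_amplitude` inverts the per-cycle swelling statistic: it
root-finds the 0%-O2 equilibrium amplitude such that the statistic evaluated
on the exact noise-free trace equals a requested percentage.  The most
hypoxic level receives the free amplitude, the least hypoxic level 1.0, and
intermediate levels sit a fixed fraction (default 0.25) of the way up —
spheroids shrink at both 3% and 10% O2, slightly less completely at 3%.

## The phantom generator

Cells are laid out by centroidal Voronoi tessellation (10 Lloyd iterations
on a dense in-disk grid) of the spheroid mid-plane — a stand-in for packed
epithelial geometry with realistic area scatter (CV ≈ 15–25%).  The cell
count follows 2D packing, `0.9·(R/r_cell)²`, unless given explicitly.  All
cell linear dimensions follow s(t), so true cell areas scale as s².  There
is no cell division, death, migration, or necrotic core.

Modalities:

* **brightfield** — dark disk (≈0.62 of the unit background) with per-cell
  intensity shading and mild radial darkening; optionally a faint alginate
  shell ring (−0.04) whose radius does *not* follow s(t), emulating the
  observation that shells do not swell.  The shell is drawn only in this
  modality (spheroids in the membrane study had shells removed).
* **membrane** — bright ridges (1.0) along tessellation boundaries and the
  spheroid rim over a dim interior (≈0.10 with per-cell variation).
* **dox** — the radial reaction–diffusion concentration (below), modulated
  by per-cell unit-mean lognormal brightness factors (default CV 0.3,
  emulating heterogeneous uptake) and by depth-dependent attenuation
  `exp(−path/ℓ_s)` with scattering length ℓ_s = 80 µm, where `path` is the
  tissue thickness traversed to the imaged plane — this reproduces the
  optically darker spheroid core.

Every rendered plane is blurred with the Gaussian two-photon PSF and then
carries Poisson photon noise (default 200 counts at unit intensity, giving
edge SNR ≈ 6) plus additive Gaussian read noise (σ = 0.01).  Z-stacks render
sphere cross-sections of the mid-plane tessellation (an approximation: no
true 3D cell packing), with slices descending from just above the unswollen
top surface at the configured spacing.  Identical `(params, schedule, seed)`
are bit-reproducible; per-spheroid and per-modality RNG streams are spawned
deterministically from the seed.

### Two-photon PSF

The Gaussian-approximation 1/e widths of the two-photon excitation PSF:

    ω_xy = 0.320 λ/(√2 NA)            NA ≤ 0.7
    ω_xy = 0.325 λ/(√2 NA^0.91)       NA > 0.7
    ω_z  = (0.532 λ/√2) · 1/(n − √(n² − NA²))

At λ = 810 nm, NA = 1.05, n = 1.33 (water dipping) these give
ω_xy = 0.178 µm and ω_z = 0.593 µm, matching the 0.18/0.60 µm printed for
that objective to within rounding.  The axial form requires NA < n.

### Doxorubicin field

Drug concentration in a sphere bathed at C = 1 obeys

    ∂C/∂t = D (1/r²) ∂/∂r (r² ∂C/∂r) − k C ,  C(r,0)=0, C(R,t)=1

with no flux at the centre.  Defaults: D = 60 µm²/min (small-molecule
diffusivity in dense tissue), k = 0.02 /min (first-order cellular uptake).
The substitution u = rC reduces this to a 1D diffusion–decay equation with
Dirichlet ends, solved by implicit Euler (default dr = R/200,
dt = 0.25 min).  Implicit Euler was chosen over Crank–Nicolson because its
M-matrix structure guarantees the physical monotonicities (C non-decreasing
in time, non-increasing edge→centre) on coarse grids, where Crank–Nicolson
oscillates; the O(dt) error is ≲0.3% at the default step against the
analytic steady state `C(r) = (R/r)·sinh(r√(k/D))/sinh(R√(k/D))`.
The centre value uses the odd-symmetry limit C(0) = u(r₁)/r₁.

## Segmentation

**Spheroids** (transmitted light or fluorescence): the spheroid is the
*textured* object on a smooth background.  Stage one localizes it: Gaussian
denoise (σ = 2 px), local variance in a 15 px window, Otsu threshold on
log-variance (the log compresses the bright edge-ring mode that otherwise
captures Otsu), closing (disk 5 px), hole filling.  Stage two re-draws the
boundary at the intensity midpoint between the object core and the
background, removing the half-window halo that the variance transform
spreads outward; if the object has texture but no intensity contrast the
halo is eroded away instead.  Finally objects below 400 px are dropped and
the object policy applied — `largest` by default (one spheroid per
hydrodynamic trap), `all` for multi-object fields.  Without the stage-two
refinement the segmented edge overshoots by roughly half the variance
window; this is exactly the edge-overestimation artefact that motivates the
guard depth in the penetration analysis.

**Tracking**: per-frame detections link to the nearest existing track
centroid within a 30 µm gate (trapped spheroids barely move), ties breaking
toward larger objects.  Internal gaps of ≤ 2 frames are filled by linear
interpolation of area and centroid and flagged `interpolated`; longer gaps
leave the track incomplete.

**Cells** (membrane stain): marker-controlled watershed.  The spheroid mask
is first eroded by one ridge-width (the stage-two boundary sits one blurred
ridge outside the outermost membrane, and watershedding that unreliable rim
produces spurious fragments).  Markers are h-minima of the smoothed image
(σ = 1 µm), with h = 10% of the in-mask dynamic range; the watershed floods
up the membrane ridges.  Regions outside 20–500 µm² are flagged under/over
size; regions touching the image border or the mask rim are counted (they
are real cells) but excluded from area statistics, since their areas are
clipped.  Cell analysis is strictly 2D per slice, matching slice spacings
too coarse for full 3D cell reconstruction.

## Swelling statistics

Area traces are normalized to 100% at their first timestamp.  Cohort
averaging resamples traces to the first trace's grid restricted to the
common overlap (linear interpolation, no extrapolation); SE = SD/√N with
N the number of spheroids.

**Per-cycle swelling** is not a standard quantity; this package fixes it
as: for each cycle, `100·(peak − trough)/trough` on the cohort-mean trace,
where the peak is searched in the cycle's most-hypoxic phase extended by a
60 min lag (accommodating the response latency) and the trough in the
preceding shrink interval (from the end of the previous cycle's peak window;
from the trace start for cycle 1).  An alternative `full_cycle` peak window
is available; the default is the hypoxic-phase window.  The summary reports
mean and SD across the first `n_cycles` (default 3) cycles — SD across
cycles, not SE across spheroids, matching the convention of the quantity it
mirrors.  The statistic is invariant to joint time shifts of trace and
schedule and, being a ratio, to any constant multiplicative segmentation
bias.

**Cell-size comparisons** pool retained cell areas across a condition's
spheroids per timepoint (mean, SE over pooled cells, percent change from
the first timepoint) and compare conditions by the two-sided Mann–Whitney U
test (tie-corrected normal approximation, via scipy; the package's tests
verify U against exhaustive pair counting).

## Uptake quantification

The representative slice is the one nearest a target depth (default 40 µm)
below the detected top surface — the first slice whose foreground area
exceeds 20% of the stack's maximum; depth ties resolve to the shallower
slice.  Accumulation is mean intensity in the segmented region, per slice
and pixel-count-weighted across the stack (equal to the 3D mean over the
imaged volume — a choice; intensity-weighted alternatives would emphasize
bright slices).  The per-slice median intensity outside the mask is
subtracted by default to stabilise cross-condition comparison.  Penetration
profiles bin mask pixels by Euclidean distance transform depth from the
segmented edge (default 2 µm bins); bins shallower than a 10 µm guard depth
are flagged because edge over-segmentation inflates them from the
background upward (the rising-limb artefact), and empty bins carry NaN.

## Phantom cohort studies

`spherox.studies` fixes three brightfield swelling cohorts (5 shell-free
spheroids of 70–80 µm radius under 2 h 0%/6 h 3%/4 h 10%; 6 in-shell
spheroids of 42–48 µm under 2 h/2 h/2 h; 5 in-shell under 3 h 0%/6 h 10%),
each programmed via amplitude calibration to per-cycle swelling of 14%,
7.1% and 11% respectively, imaged every 30 min for three cycles at default
noise, and analysed by the full pipeline.  The membrane study renders two
cohorts of three 150 µm spheroids (≈560 cells each in the imaged plane,
≥1300 retained cells pooled per condition per timepoint) at seven
timepoints 40 min apart: the 0%-O2 cohort carries first-order cell-area
swelling reaching ≈11% at the final timepoint with τ = 60 min (consistent
with the sub-hour onset), the 20%-O2 control is static.  Problem sizes
(160–352 px fields, ≤73 frames) keep a full study run under a minute per
cohort on one core while leaving ≥10 px per cell and ≥6 samples per
swelling cycle.

## What passing tests do and do not show

The phantom reproduces the *statistical and optical structure* the analysis
assumes: programmed first-order swelling, near-uniform tessellated cells,
an edge-bright reaction–diffusion drug gradient with lognormal per-cell
heterogeneity, Gaussian PSF blur, Poisson+read noise, a static shell ring.
It does not emulate cell migration or division, necrotic cores, 3D cell
packing (Z-slices are scaled cross-sections of one mid-plane tessellation),
uneven illumination, stage drift, debris, or stain internalization.
Parameter-recovery results therefore demonstrate that the pipeline is
unbiased and precise under its own model assumptions, not that it would
meet the same error bars on arbitrary real microscopy.

## Known limitations

* τ and the equilibrium swelling amplitudes are not independently measured;
  only their product with the schedule (the per-cycle statistic) is
  exercised.
* Spheroids taller than the culture channel are physically compacted;
  projected area then over-states volume change.  The phantom represents
  this only as an optional scalar inflation of the area change on
  shell-free spheroids (`confinement_gain`), not as 3D mechanics.
* The dox field uses one radius per rendered field of view; mixed-radius
  multi-spheroid fields reuse the largest radius' profile.
* Mann–Whitney p-values use the asymptotic method throughout; exact-method
  p-values differ for very small samples (n ≲ 8).
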