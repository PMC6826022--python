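# Methods

This note documents the models, algorithms and numerical choices behind each
pipeline stage, what the synthetic generators do and do not emulate, and the
design decisions taken where the underlying measurement procedures left the
implementation open.

## Beating-heart video mechanics

**Chamber model and ground truth.** The synthetic ventricle is a prolate
ellipsoid with equal short-axis semi-axes `a = b` and long semi-axis
`c = 1.5·a`. Its volume follows a raised cosine between ESV and EDV at the
pacing rate (end-diastole at `t = 0`): a smooth waveform with exactly one ED
and one ES per cycle. For this geometry the biplane area–length estimate
`V = (2/3)·(πa²)·(2c) = (4/3)πa²c` equals the true ellipsoid volume, so the
simulator's ground truth is analytic and the whole chain can be checked
against it. Defaults emulate the acquisition protocol: 2 Hz pacing, 66 fps,
3 s of recording (6 cycles), 0.02 mm/pixel on 192×192 frames with EDV = 4 and
ESV = 2 mm³ — chamber volumes of a few mm³ being the realistic scale for an
adult zebrafish ventricle. Rendering uses a bright silhouette (220) on a dark
background (20), optional Gaussian blur (default σ = 1 px, a mild optical
point-spread surrogate) and additive Gaussian pixel noise.

**Segmentation.** The measurement procedure being reproduced used unspecified
"edge detection"; here each frame is segmented by Otsu global thresholding,
morphological closing (disk radius 2), hole filling and retention of the
largest connected component, with a configurable minimum-area floor
(default 50 px) below which segmentation fails loudly. This choice is simple,
deterministic and validated against analytic disks (area within 1 %).

**Geometry.** Area is the pixel count times `pixel_size²`. The long-axis
length is the silhouette's caliper extent along its principal axis
(eigenvector of the coordinate covariance), measured as the projection span
plus one pixel to account for pixel extent. Ray radii are measured from the
foreground center of mass along `n_rays = 36` equally spaced directions by
quarter-pixel ray marching with nearest-pixel lookup; 36 rays keep the
radius CV below 2 % on a discretized disk while remaining cheap.

**Cycles and indices.** End-diastole/end-systole are volume maxima/minima
found with a minimum peak separation of 0.7 pacing periods; the trace is
padded so a boundary frame can serve as ED, and detection fails if the cycle
count deviates from the pacing-implied expectation by more than one. EF, FS
and FAC are computed per cycle from the volume, long-axis length and
short-axis area at the cycle's own ED and ES frames, then averaged over all
detected cycles (at least three are required).

**Strain, velocity, loops.** Radial strain within each cycle is
`(r̄(t) − r̄_ED)/r̄_ED` referenced to that cycle's ED frame — zero at ED and
negative in systole. Before differentiation the strain is smoothed with a
Savitzky–Golay filter (window 7, order 2, configurable; window 1 disables
it), because finite differences of pixel-quantized radii are noise-dominated.
Velocity is the centered gradient of the smoothed strain; the most negative
and most positive values are the maximal contraction and relaxation
velocities. The velocity–strain loop area is the absolute shoelace-polygon
area over one cycle's frame-ordered vertices; the loop must close in strain
within a tolerance (default 0.05) and is reported in strain²/s without
further normalization, since no standard normalization exists for this
index.

## Doppler indices

E and A peaks are velocity maxima with prominence above 10 % of the global
maximum, paired in temporal order within each cycle (the generator places
each cycle's systolic intervals before the diastolic filling window, so the
first lobe of a pair is E). E/A is the ratio of cycle-averaged peaks. IVCT,
IVRT and ET are taken from valve-event annotations
(`IVCT = vb_open − av_close`, `ET = vb_close − vb_open`,
`IVRT = av_open − vb_close`, averaged over cycles) and combined into
`MPI = (IVCT+IVRT)/ET`. An inflow trace alone cannot localise the
ventriculobulbar valve events, so without annotations the intervals and MPI
are reported as unavailable rather than inferred — no guessing. Default
simulated timings (period 0.5 s, IVCT 40 ms, ET 180 ms, IVRT 50 ms, E 18 and
A 14 mm/s) are plausible anesthetized-adult values and satisfy
`IVCT+IVRT+ET < period` by construction.

## Myofibril kinetics

**Trace model.** Phases are delimited by protocol marks (activation onset,
release, restretch, relaxation onset). The generator produces: passive force,
then `f_p + (f_max − f_p)(1 − e^{−k_act t})`; zero force between release and
restretch (slack fibre); redevelopment `f_max(1 − e^{−k_tr t})`; then
relaxation — a linear decline with slope `k_lin·(F_r − f_p)` for `t_lin`
seconds followed by exponential decay at `k_rel` to the passive force,
continuous at the breakpoint. Defaults (f_max 500 nN, passive 50 nN,
CSA 10 µm² → 45 mN/mm² developed tension; rates of order 5–10 s⁻¹ and
T_LIN 50 ms, appropriate for cardiac myofibrils at 10 °C; 1 kHz sampling)
give every fitted window several time constants of data.

**Rise fits.** `k_ACT` and `k_TR` use bounded least squares on
`F = F₀ + (F_∞ − F₀)(1 − e^{−kt})` with all three parameters free, the rate
initialised from the half-rise time (`ln 2 / t_half`), and no random
restarts (determinism). Windows with dynamic range below a floor raise an
insufficient-rise error; a window shorter than `2/k` triggers a warning.
Fitted rates are invariant to force rescaling and time-origin shifts.

**Biphasic relaxation.** The breakpoint `T_LIN` is chosen by exhaustive
search over candidate sample times minimising the total SSE of a linear fit
before the candidate plus a one-parameter exponential (amplitude fixed by
continuity, decaying to baseline) after it. For long windows the grid is
coarsened to at most 120 candidates and then refined to single-sample
resolution around the optimum, which preserves exact recovery on noiseless
data while bounding cost. A best breakpoint at the end of the grid means the
data show no exponential tail and the fit fails loudly (this is how a purely
linear decline is rejected). `k_LIN` is the linear slope magnitude divided by
the developed force, giving units of 1/s comparable across fibres — the
normalization is a package choice, stated here because conventions differ.
Monotonicity is checked on a smoothed copy of the window (rises above 0.1 %
of developed force on a ~5 % moving average), warning when more than 20 % of
samples rise.

**Tension, Hill fit, rundown.** Maximal tension is
`(plateau − baseline)/CSA`; CSA is a required input and tension fails
without it rather than assuming a default. The Hill fit
`F = F_max/(1 + 10^{n_H(pCa − pCa50)})` is initialised at the half-max point
with `n_H = 2` and needs at least four distinct pCa values. Rundown is
`(first − last)/first` over a set of contractions; fibres above 20 % are
flagged for exclusion.

## Morphometry

All fraction measurements operate on caller-supplied masks/ROIs (standing in
for manual outlines) or threshold intensity images with Otsu's method
computed inside the ROI, which makes them invariant to affine intensity
rescaling. Nuclei are connected components with pixel area in a
configurable [20, 2000] px band (at ~1 µm/px) — debris and merged clumps are
excluded deterministically and counted in diagnostics. A nucleus is positive
when its mean positive-channel intensity exceeds a threshold (default: the
midpoint of the channel's range, which degrades gracefully to "none
positive" when the positive channel is flat). The nuclei generator enforces
a two-pixel clearance between nuclei so 8-connected labelling can never
merge them; real tissue has touching nuclei, so on real images the size
bounds, not the generator's guarantee, do that work.

## Cohort statistics

**Ucrit.** The swim protocol's printed formula carries an ambiguous symbol
assignment (the increment printed where the standard protocol has the final
stage's speed); the implementation follows the standard stepwise form
`Ucrit = Ui + ΔU·(t/T)` it derives from, with `Ui` the last completed
stage's speed. Exhaustion within the first stage is a protocol error rather
than an extrapolation. The generator inverts this formula exactly, so
round-trip recovery is to machine precision.

**Survival and group tests.** Kaplan–Meier estimation and the log-rank test
delegate to lifelines (ties follow the standard simultaneous-risk-set
convention; censored times tied with events stay at risk through the event);
an independent hand-written O/E/V log-rank computation serves as the test
oracle. t-tests (pooled variance), one-way ANOVA and Tukey HSD delegate to
scipy. All-censored data and single-group inputs are errors, as is zero
pooled variance with unequal means. Repeated-measures (mixed) designs are
out of the computational core; the CLI emits tidy tables usable by external
mixed-model tools.

## Synthetic data: what it does and does not emulate

The generators reproduce the *geometry, kinetics and bookkeeping* of the
assays — volumes, time constants, protocol timings, exact fractions — under
additive Gaussian noise, the simplest model that exercises robustness. They
deliberately do not emulate myocardial texture, optical vignetting or motion
blur, Doppler spectral physics, force-transducer drift, staining variability
or touching nuclei. Passing recovery tests therefore demonstrates
correctness of the computations and robustness to uncorrelated noise, not
performance on raw laboratory images; segmentation and detection parameters
are expected to need tuning on real data. All randomness flows from explicit
seeds (`numpy.random.default_rng`); generators are pure functions of their
parameter sets, and identical parameters give bit-identical outputs.

## Problem sizes and determinism

The validation suite and the acceptance script use the study-scale defaults:
3 s videos (198 biplane frame pairs) with 10 noisy replicates, 6 s force
traces at 1 kHz with 50 noisy replicates, 1000 simulated two-group survival
cohorts of 30 animals per group for the null calibration of the log-rank
test, and 100-nucleus images. Every nonlinear fit uses deterministic
initialisation; there is no global random state anywhere in the package.
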