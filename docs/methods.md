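# Methods

`spermwall` analyses 2-D trajectories of sperm heads swimming near a
roughly straight uterine wall, as recorded in fluorescence time-lapse
movies. This note documents the models and procedures the package
implements, the choices made where the design was genuinely open, and what
the synthetic-data generator does and does not emulate.

## Kinetic parameters

For a trajectory of spots $p_0 \dots p_{n-1}$ spanning frames
$f_0 \dots f_{n-1}$ at frame rate $\mathrm{fps}$, with duration
$T = (f_{n-1} - f_0)/\mathrm{fps}$:

* **VCL** (curvilinear velocity, µm/s) $= \sum_i \lVert p_{i+1}-p_i\rVert / T$.
  A gap-closed missing frame contributes a single straight segment between
  its flanking spots; no interpolation is performed.
* **VSL** (straight-line velocity, µm/s) $= \lVert p_{n-1}-p_0\rVert / T$.
* **LIN** (linearity of forward progression) $= \mathrm{VSL}/\mathrm{VCL}
  \in [0,1]$.
* **SWR** (straight line-to-sideward movement ratio): the track
  displacement divided by the *maximum sideward movement distance* — the
  width of the narrowest band parallel to the displacement line containing
  every spot, i.e. the peak-to-peak extent of spot projections on the unit
  normal of the first→last direction. For the perpendicular projection
  used here, the band over the polyline equals the band over the spot set,
  so only spot positions enter.

Degenerate values are explicit *undefined* markers (NaN), never zero: LIN
when VCL = 0, SWR when the displacement is zero (closed track) or the band
width falls below $10^{-9}$ µm (perfectly straight track). Downstream
statistics drop undefined rows and report the count, so degenerate tracks
cannot bias a fit toward zero. VSL ≤ VCL holds by the triangle inequality;
LIN is clipped at 1 against rounding. All four parameters are invariant
under rigid motions; VCL/VSL scale linearly under spatial rescaling while
LIN and SWR are scale-free — all verified as property tests.

## Wall geometry

The wall is a straight line fitted to the boundary pixels of a binary wall
mask. Boundary = foreground pixels with a background 4-neighbour; the
image border does not count as background, so a half-plane mask yields
only its true edge. Fitting is ordinary least squares of the minor-extent
coordinate on the major-extent one (y on x when the x-range dominates,
else x on y), which keeps near-vertical walls well-posed; an orthogonal
total-least-squares fit is available as an option. The reported residual
is the RMS perpendicular distance of the boundary points to the line.

Each trajectory contributes two covariates:

* **distance**: perpendicular distance from the *temporal midpoint spot*
  (index $\lfloor (n-1)/2 \rfloor$) to the line. The midpoint spot, not
  the centroid, is the default because the distance is defined for a
  single point of the track; the centroid is available behind a switch.
* **angle**: acute angle in $[0, \pi/2]$ between the first→last
  displacement line and the wall direction,
  $\arccos\lvert u \cdot w\rvert$. The sign of travel along the wall is
  deliberately discarded.

## Turn classification

Each sperm carries a fixed hook side — "left" or "right" of its heading,
with "left" meaning a positive cross product heading × vector. The
classifier finds the first spot within the contact threshold (2 µm, about
one head length; no empirical contact rule exists, so this is a package
constant exposed in configuration), averages headings over k = 3 frames on
each side of contact, and labels the turn **pro** when the post-contact
along-wall direction lies on the hook side of the pre-contact heading,
**anti** otherwise, **none** without contact. Mirror-imaging the scene and
flipping the hook side preserves the label (chirality consistency, tested).
On noise-free simulated turns the classifier agrees with the generative
labels on ≈ 99% of events (the residual disagreements are grazing,
near-parallel approaches where the hook side of the approach heading is
numerically ill-determined); agreement degrades gracefully with heading
diffusion and is reported, not asserted, in that regime.

## Tracking

A deliberately simplified single-particle tracker in the TrackMate mould,
faithful to the parameters that matter for these movies:

1. **Detection**: Gaussian smoothing (default σ = 1 µm), Otsu threshold
   (an absolute threshold is available), 8-connected components,
   intensity-weighted centroids; equivalent-disc radius
   $\sqrt{A/\pi}\,\cdot$ pixel size must exceed 0.75 µm (a minimum
   head-size gate).
2. **Linking**: per consecutive frame pair, a gated linear assignment
   problem — link cost $d^2$, links with $d >$ 11 µm forbidden, and a
   non-link alternative priced at the squared gate (Jaqaman-style
   padding). Because $d^2 \le \mathrm{gate}^2 < 2\,\mathrm{gate}^2$, the
   optimum is the maximum-cardinality matching of minimum total squared
   distance; this is verified against exhaustive enumeration on instances
   with ≤ 5 spots per frame.
3. **Gap closing**: a second assignment over segment (end, start) pairs
   with frame gap 1–2 and distance ≤ 11 µm; chains of accepted merges are
   concatenated, missing frames stay absent.
4. **Filters**: ≥ 7 spots per track (i.e. more than 6) and net
   displacement > 2.5 µm. The displacement gate is read as a *minimum*
   (an upper gate of 2.5 µm would discard nearly every motile track); it
   removes immotile debris, is configurable, and every rejection is
   reported with its reason.

Ties in the assignment are made reproducible by processing spots in
(frame, x, y) order; outputs are deterministic. Splitting/merging costs,
Kalman prediction, sub-pixel Gaussian fitting, and image registration are
out of scope — synthetic stacks are generated drift-free.

## Statistics

**Directional test.** With $n$ wall-contact turns of which $k$ are pro,
the exact one-tailed binomial test computes
$p = \sum_{j=k}^{n} \binom{n}{j} 0.5^{n}$, and the one-sided 95%
Clopper–Pearson lower bound is the $p_0$ solving
$P(X \ge k \mid p_0) = 0.05$ (0 when $k = 0$), interval $[p_0, 1]$.
Clopper–Pearson is used because it is the exact inversion of the same
binomial tail; no other interval is offered. For the reference counts
52/63 this gives proportion 82.54%, $p = 8.4\times 10^{-8}$, bound 0.728.
Note the exact test is conservative: at $n = 63$ and nominal α = 0.05 the
rejection region is $k \ge 39$ with true size 3.85%, so Monte-Carlo
rejection rates under a 50/50 null are expected slightly below 5%.

**Kinetics regressions.** Log-transformed VCL, VSL, LIN and SWR are
regressed by OLS on wall distance and angle plus an intercept (natural
log; non-positive responses become undefined before the transform, with a
logged count). All four responses default to the log transform, with a
per-response switch rather than a hard-wired exception for LIN. This is
the fixed-effects reduction of the mixed models appropriate for real
multi-animal data: synthetic data has no animal or session structure to
pool over, and the estimand of interest here is recovery of the fixed
effects; group-indicator covariates (e.g. a per-batch `cropped` flag or
animal codes) can be added as columns. Rank-deficient designs and fits
with fewer than 10 usable rows are refused; a zero-variance response is
flagged degenerate. Variance-inflation diagnostics and random-effect
estimation are out of scope. No multiple-testing correction is applied
across the four models.

**Group comparison.** `compare_groups` returns per-group median, quartiles
and n of the four parameters (boxplot summaries, e.g. sperm trains vs
single sperm); deliberately no hypothesis test.

## Synthetic data generator

Each sperm is a persistent random walk in µm coordinates. At each frame
its log speed follows the generative law

$\log s_t = \beta_0 + \beta_d\, d_t + \beta_\theta\, \theta_t +
\varepsilon_t$, $\varepsilon_t \sim N(0, \sigma_s)$,

with $d_t$ the perpendicular wall distance, $\theta_t$ the acute angle
between heading and wall, and the heading subject to Gaussian angular
diffusion. On entering the 2 µm contact zone a turn event fires once
(re-armed after leaving the zone): with probability `pro_hook_prob` the
new heading is the along-wall direction on the sperm's hook side; otherwise
it is the along-wall direction on the opposite side lifted π/4 rad into
the lumen, so an anti turn leaves the wall. A specular *reflection* was
considered for the anti branch and rejected: reflection is achiral — its
along-wall sense equals that of the approach — so roughly half of
reflected "anti" turns would present pro-side geometry and no observer
could recover the labels; the chiral anti model keeps the label an
observable property of the trajectory, matching how such turns are scored
from video. Hook sides are fixed per sperm, sampled 50/50 at birth
(anatomy, not state). Positional measurement jitter is added per spot.
Positions that would cross the wall line are reflected back, and rendered
head centres are clipped to the field.

Defaults are the study conditions: 512×512 px at 1 µm/px, 30 fps,
60-frame (2 s) clips; $\beta_0 = \log 80$ (≈ 80 µm/s at the wall swimming
along it), $\beta_d = -0.02$/µm, $\beta_\theta = -0.5$/rad,
$\sigma_s = 0.1$ log-units, angular diffusion 0.2 rad/frame, jitter
0.3 µm, `pro_hook_prob` = 0.8254 (the observed pro proportion). One global
seed drives counter-derived per-sperm substreams, so track $k$ is
bit-reproducible independently of `n_sperm`.

The generator's `frame_records` table exposes the covariates and log
speeds the model actually used — the oracle for recovery tests. Slope
recovery is assessed on per-track means of these records (mean log speed
vs mean distance/angle), which inherits the generative linearity exactly
with independent per-track noise. Regressing *measured* log VCL on the
*midpoint-spot* distance instead is attenuated toward zero
(errors-in-variables: the covariate drifts over a 2 s track); the package
computes that pipeline-level fit too and reports it descriptively, which
is worth remembering when interpreting distance effects fitted to real
per-track summaries.

Rendering: isotropic Gaussian head blobs (σ = 1 µm, peak 4000 counts on a
100-count background), optional trailing midpiece blob in a second
channel, wall half-plane darkened (×0.2), Gaussian read noise (σ = 20),
16-bit quantisation. Heads-only rendering suffices because the tracker
targets heads; there is no flagellum, hydrodynamics, wall curvature,
sperm–sperm interaction, train formation, stage drift, or uterine
contraction in the model. Passing tests therefore demonstrate the
*analysis* chain is correct and calibrated under the stated generative
model — not that the model captures everything in real uterine movies.

## Problem sizes and numerical conventions

Test and acceptance runs use desk-scale sizes chosen to make the Monte
Carlo error small relative to the asserted tolerances: 500 simulated
tracks for slope recovery (recovery within 2 SE), 500 replicates for the
power of the directional test at the observed proportion, 1000 replicates
for its type-I rate, ≥ 1000 random trajectories for the SWR oracle (agreement
to 1e-9 relative), ≥ 1000 simulated wall contacts for the turn-label
frequency (within 3 binomial SDs), and a 16-sperm 60-frame 512×512
rendered stack for end-to-end tracker recovery (spot-set Jaccard ≥ 0.9).
Forbidden assignment costs use a large finite constant (1e30), gates are
inclusive (≤), and equal-cost optima are resolved by sorted spot order.

## Known limitations

* The instantaneous-turn model is a stand-in: real turns take several
  flagellar beats, and no pivoting kinematics are simulated.
* Walls are straight lines; curved walls must be cropped to straight
  segments before analysis.
* The tracker has no motion model; it will swap identities if sperm
  approach within the linking gate of each other between frames.
* The fixed-effects regression understates uncertainty for clustered real
  data (repeated animals/sessions); its interface accepts group-indicator
  columns but offers no partial pooling.
* Which real image batches were cropped is not recoverable; a per-batch
  `cropped` covariate can be carried through the stats table but cannot
  reproduce any original assignment.
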