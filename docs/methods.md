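# Methods

## Model

Each of SO and LG+PL is a Hill-type lumped actuator: a contractile element
(CE) with series and parallel elastic tissue, joined to the skeleton
through proximal and distal tendons.  Because all contractions are
isometric and muscle–tendon unit lengths are held constant across
conditions, the lumped muscle force F_CE + F_PE is treated as a constant
per recording, and all forces resolve through static equilibrium; the
inertial node masses are inert and are not modelled.

Three epimuscular pathways connect LG+PL to its surroundings, each a
massless elastic element whose transmitted force depends only on the
SO/LG+PL relative position P_R:

* **INT** — the intermuscular myofascial tissue at the SO/LG+PL belly
  interface (proximal and distal parts lumped into one element);
* **NV1** — the neurovascular tract running between SO and LG bellies
  (leads force both intermuscularly and out of the group);
* **NV2** — the tract from the popliteal fossa to the gastrocnemii
  (leads force outside the synergistic pair only).

The static balances at the proximal and distal LG+PL tendon nodes are

    F_prox − F_NV2 − F_muscle = 0
    F_dist − F_muscle + F_INT + F_NV1 = 0

so the measurable tendon force difference ΔF_LGPL = F_prox − F_dist equals
F_INT + F_NV1 + F_NV2 — the net epimuscularly transmitted force.

Collagenous tissue recruits fibres progressively with stretch, which
motivates a piecewise-linear force–displacement law: each pathway has
segment stiffnesses K1..K3 on the displacement-magnitude bands [0,1],
[1,2], [2,3] mm.  Segments are anchored at the reference position P_R = 0,
where ΔF_LGPL is zero by observation, and negative displacements use odd
symmetry F(−P) = −F(P) by default (a fit with independent negative-side
segments is available).  Stiffness values are signed: in the bundled
calibrations NV2 carries the opposite sign to INT and NV1, encoding its
oppositely oriented force-transmission vector.  Evaluation outside the
fitted ±3 mm span raises an error rather than extrapolating.

Internally all forces are N and displacements mm; the conventional mN/mm
stiffness scale appears only in file formats and reports.

## Calibration (three-condition estimator)

With both LG+PL tendons repositioned together over −3…+3 mm in 1-mm steps
and forces recorded intact, after resecting INT (post I) and after
additionally resecting NV1 (post II), the per-position pathway forces are

    F̂_INT = ΔF_intact − c·ΔF_postI + (c−1)·ΔF_postII
    F̂_NV1 = ΔF_postI − ΔF_postII
    F̂_NV2 = ΔF_postII

The dimensionless parameter c (default 0.9, admissible (0, 1]) is the
ratio of NV1 tract length before versus after resection of the myofascial
linkages: once those linkages are cut the tract is slightly longer and
stretches differently, so its contribution while they were intact is
discounted by c.  The estimator is linear in the inputs and satisfies the
exact identity F̂_INT + F̂_NV1 + F̂_NV2 − (1−c)·F̂_NV1 = ΔF_intact.  Its
sensitivity to c is reported as the RMSE of F̂_INT(c) − F̂_INT(0.9) over
positions, as a percentage of mean |F̂_INT(0.9)|; analytically this equals
|c − 0.9| · RMS(F̂_NV1) / mean|F̂_INT(0.9)| · 100, which the implementation
reproduces to rounding error.

Segment stiffnesses are force increments across each band divided by the
band width; with symmetry averaging (default) each positive-side slope is
averaged with its mirrored negative-side slope.  Group values are obtained
by fitting each animal first and averaging the per-animal stiffnesses
(matching mean ± SD reporting), not by fitting the mean curve.  The
complete isolation (post II) was feasible in one animal of the normal
group only, so its ΔF series is shared group-wide; a series borrowed from
another group can be supplied explicitly.

Estimation runs on total (active) forces only.  In the passive state the
LG+PL force difference is not balanced by the measured SO tendon — force
escapes through the intact proximal SO insertion and other unmeasured
structures — so the model's premise fails; a passive-state override exists
for exploration and warns when used.

## Prediction and validation

When only the proximal LG+PL tendon is repositioned, the intermuscular
interface is loaded less than under whole-muscle repositioning.  The
per-segment scale factors r (bundled values 0.07, 0.13, 0.21, estimated
from a distal-only-resection subset as the per-segment ratio of
intermuscular force under the two loading modes) discount K_INT in the
prediction

    ΔF_mod(ΔP) = ΔF_mod(0) + Σ_j (r_j·K_INT,j + K_NV1,j + K_NV2,j)·w_j

summed over segments crossed.  With r = 1 this reduces exactly to the
calibration forward model.  The reference offset ΔF_mod(0) defaults to 0
(no net transmission at the reference position) and can be set to a
measured value.

Agreement between measured and predicted series is summarised by the
Bland–Altman bias (mean of measured − predicted) and limits of agreement
bias ± 1.96·SD, using the sample (n−1) standard deviation — standard
practice where the convention is not otherwise fixed.  An OLS regression
(scipy.stats.linregress) of measured on predicted, and of ΔF_SO on
ΔF_LGPL for calibration data, provides slope/intercept/R.  A
percentage-of-range transform is provided for pooling animals with
different force ranges on one agreement plot.

## Synthetic experiment

The generator emulates the in situ protocol so every stage is testable
without animal data.  Defaults are the experimental conditions: 7 positions
−3…+3 mm, plateau forces 11.5 N (LG+PL proximal) and 1.3 N (SO distal) at
the reference position, 500-ms tetanus at 1 kHz sampling with conditioning
twitches 1.5 and 1.0 s before onset, 7 animals per group, and additive
i.i.d. Gaussian noise of SD 0.05 N per extracted force — of the order of
the between-animal spread of the reported plateau forces, since no
within-measurement noise model is reported.

Condition structure.  The ground-truth NV1 stiffness describes the tract
in its post-resection state (the only state in which it is observable in
isolation), so the intact force difference is generated as
ΔF_intact = F_INT + c·F_NV1 + F_NV2, post I as F_NV1 + F_NV2 and post II
as F_NV2.  With this convention the three-condition estimator inverts the
generator exactly, and the noiseless round trip (truth → synthetic data →
estimator → stiffness fit) reproduces every segment value to floating-point
precision — the basis of the recovery tests.

Channel layout.  The proximal LG+PL tendon carries the constant baseline;
the distal tendon carries baseline − ΔF_LGPL.  The SO distal tendon
receives a fraction `so_coupling` (default 0.3) of the force routed through
INT and c·NV1; the remainder exits through the intact proximal SO insertion
and other structures that the experiment does not instrument.  The value
0.3 keeps the SO channel physical (total ≥ passive) across the whole ±3 mm
range even for the stiff TI truth, while preserving the defining
qualitative feature of the calibration data: a positive, tight linear
relation between ΔF_SO and ΔF_LGPL.  NV2 never loads SO.  Waveform shapes
(half-sine twitches, 30-ms rise, exponential relaxation) are schematic;
only the two 50-ms extraction windows are load-bearing, and the noiseless
waveform is exactly flat over both, so extraction is bias-free by
construction.

What the generator does not emulate: history effects and fatigue between
contractions, belly deformation and non-uniform strain, passive-state
nonlinearity (passive baselines are position-independent), between-animal
variation in the true stiffness (animals differ only by noise), and the
fast SO relaxation transient.  Passing recovery tests therefore show the
estimator is correct and unbiased under the model's own assumptions, not
that those assumptions hold in tissue.

## Numerical choices

* Equality tolerances: force balances and round trips are asserted at
  1e-9 N (the estimator chain is exact up to floating point).
* Positions are matched to breakpoints with a 1e-9 mm tolerance; a missing
  breakpoint position is a structural error, never interpolated silently.
* The position→knee-angle map is affine with the reference position fixed
  at 90°; the default slope of 10 deg/mm is an illustrative order of
  magnitude for the rat knee and should be replaced by joint-geometry data
  when the map matters.
* Monte-Carlo test sizes: 200 replicates of 7-animal groups for
  unbiasedness, 200 replicates at group sizes 1 and 4 for the 1/√n spread
  scaling — large enough for 3-SE assertions to be stable at the default
  seed policy, small enough to keep the suite fast.
* Bland–Altman regression fields degrade to NaN (rather than raising) when
  the fit is degenerate, since the bias and limits remain well defined.

## Known limitations

* The estimator shares one post-II series per group; with a single donor
  animal, NV2 estimates inherit that animal's noise undiluted, and NV1/NV2
  segment values (an order of magnitude below INT) are noisy at realistic
  noise levels — unbiased, but individually meaningful only on average.
* The proximal-only scale factors r are taken as known inputs when
  predicting; estimating them requires a distal-only-resection experiment,
  which the generator does not emulate.
* The bias and limits obtained against real testing data depend on that
  data's physiological length range, which the simulator does not model;
  the validation closure tests only internal consistency.
* c is a parameter, not an output: the package does not infer it from
  anatomy.
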