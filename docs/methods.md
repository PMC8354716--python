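# Methods

## Model and assumptions

The package treats a two-timepoint cohort as draws from the generative model

    β_{i,v}(s) = f_v(a_i + s) + c_v · b_i + ε_{i,v},   s ∈ {0, 5},

where `f_v` is a smooth per-voxel age trajectory, `a_i` the integer baseline
age, `b_i = a_i − mean(a)` the participant's birth offset (years born earlier
than the sample-average birth date), `c_v` a voxel-wise cohort effect in
activation units per birth-year, and ε i.i.d. Gaussian noise. The cohort term
is constant within participant across timepoints. Under this model:

* the longitudinal estimator (kernel-weighted mean of follow-up − baseline)
  has expectation `f_v(t+5) − f_v(t)` — the cohort term cancels exactly;
* the cross-sectional estimator (difference of kernel-weighted baseline
  templates at t and t+5) has expectation `f_v(t+5) − f_v(t) + 5·c_v` plus a
  kernel-smoothing bias;
* their difference at interior target ages estimates `5·c_v`.

The method is deliberately phenomenological: no mixed-effects or parametric
growth model is fitted; curves are weighted means and their algebra.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| kernel σ | 4 | years | balances age specificity against sample noise; widths 3–5 give similar templates on smooth trajectories, asserted by a robustness test |
| target ages | 20…80 | years | the sampled baseline range; 61 templates |
| change window (lag) | 5 | years | the follow-up interval, treated as exact |
| ROI radius | 12 | mm | sphere ("searchlight") neighbourhood for local curves |
| brackets | 20–40 / 41–60 / 61–75 | baseline years | tertile-like segmentation; 21/20/15 curve points |
| tail α | 0.025 | fraction | 2.5/97.5 percentile extremes; rank-based so the tail size is exactly ⌊αN⌋ (601 per tail at N = 24,055) |

The Gaussian normalizing constant 1/(σ√2π) cancels in every weighted mean;
it is kept for fidelity to the standard density form and nothing may depend
on it.

## Numerical choices

* **No kernel truncation.** All participants contribute at every target age.
  In float64 a weight underflows to exact zero beyond ~38σ; the weight *sum*
  is always dominated by the nearest participants and never underflows for
  σ ≥ 1 over a 60-year span, so weighted means are unaffected.
* **Boundary bias.** Near ages 20/80 the kernel has one-sided support;
  division by Σw does not remove the resulting bias (≈1% of a linear slope
  at 3σ from the boundary, decaying quickly inward). No edge correction is
  applied; recovery checks are therefore evaluated at interior target ages
  (30–65).
* **ROI curves via restriction.** Because weighting, subtraction and ROI
  averaging are all linear and voxel-wise, restricting the full change-map
  series to ROI members and averaging is algebraically identical to
  weighting each voxel subset separately; the cheap route is used and the
  equivalence is asserted against a literal per-ROI re-implementation at
  tolerance 1e-10.
* **Sign-split integrals.** Trapezoidal rule at unit (1-year) spacing;
  intervals straddling zero are split at the linearly interpolated crossing
  so positive + negative equals the plain trapezoidal integral to 1e-12.
  Segments shorter than two points have zero area.
* **Zero crossings.** Exact zeros are ignored: a fluctuation requires
  strictly opposite signs on the flanking nonzero values ([1, 0, 1] is
  stable, [1, 0, −1] fluctuates).
* **Peaks.** Arg-max of |curve|; ties break toward the earliest age; an
  all-zero curve reports its earliest age with sign '+'.
* **Percentile tails.** Rank-based (top/bottom ⌊αN⌋), ties broken by stable
  original index order; interpolated percentiles would make the tail size
  data-dependent.
* **Masked-voxel order.** Fortran order (x fastest), matching the NIfTI
  on-disk layout; report coordinates are voxel centers in mm world space.
* **Determinism.** All randomness flows through `numpy.random.default_rng`
  seeded from the run seed (sub-streams keyed by domain/timepoint);
  volumes are written as uncompressed `.nii`, so a rerun is byte-identical
  and checksums match.

## Design decisions

* **Cohort-effect sign convention.** `b_i = a_i − mean(a)` with `c_v` per
  year-earlier-born, so cross-sectional minus longitudinal equals `+5c` —
  the sign a cohort decline in later-born generations would show when older
  participants carry higher offsets.
* **Longitudinal weights use baseline age**, so both measurements are
  indexed by the same baseline-age axis (window [t, t+5]).
* **Longitudinal behavioral aggregation divides by Σw** (weighted mean, not
  raw weighted sum) so the cross-sectional and longitudinal behavioral
  curves share a scale and can be plotted on one axis.
* **Stability is computed on ROI change curves**, the objects the rest of
  the analysis operates on, rather than raw voxel curves.
* **Participants missing a domain entirely are dropped from that domain
  only**; within a domain, the score is the mean over available tasks
  (at least one is required).
* **z-scoring uses the sample SD (n−1)** of baseline scores; both timepoints
  are standardized against the baseline anchor.

## The synthetic generator

`synthetic_cohort` emulates the study design: integer baseline ages uniform
over 20–80 (optionally stratified one-per-year for bias-free recovery
designs), follow-up exactly 5 years later, a 12×14×12 grid of 3-mm voxels
(2,016 mask voxels — chosen so a full four-domain run takes seconds), four
domains × three tasks, per-voxel quadratic trajectories in the centered age
variable u = (age−50)/30, optional per-voxel cohort effects, accuracy scores
clipped to [0,1] and reaction times kept positive, 10% missing task cells
repaired to respect the one-task-per-domain inclusion rule, and independent
Gaussian noise (activation SD 0.5 β-units; behavioral SD 0.03 accuracy
units, scaled ×1000 for reaction times in ms). Practice effects are exposed
as a free additive parameter, default 0, since their size is not pinned down
by the design.

What it does **not** emulate: spatial autocorrelation of activation or
noise, hemodynamic structure, attrition, scanner drift, or a realistic
gray-matter mask geometry (the mask is a filled or uniformly subsampled
box, so ROI sizes range up to the full 257-voxel sphere rather than a
brain-shaped distribution). Passing recovery tests therefore demonstrates
the estimators' algebra and identifiability under the stated model, not
robustness to spatially structured artifacts in real data.

## Evaluation designs

* **Linear-trajectory recovery** plants `f(age) = β·age` with cohort slope
  c on a 2,016-voxel grid, n = 200, stratified-uniform ages, noise-free:
  the longitudinal global curve equals 5β to machine precision and the
  cross-sectional excess matches 5c within ~2.3% at interior ages (pure
  kernel-discretization bias).
* **MAE-tail enrichment** plants a cohort effect in a contiguous 5% of
  voxels with noise SD equal to 0.25·|5c| and checks that at least 80% of
  the α = 0.025 upper-tail ROIs (by MAE between the two measurements) are
  centered on planted voxels. The tail holds ⌊0.025N⌋ ROIs while 5% of
  centers are planted, so tail membership — not coverage of all planted
  voxels — is the attainable notion of enrichment; the observed rate is
  100% against a ~27% base rate of sphere-overlap by chance.
* **Peak recovery** plants one dominant extremum per synthetic ROI curve,
  noise-free, and requires exact age and sign recovery for all ROIs.

## Known limitations

* Kernel boundary bias at target ages near the sampled range ends is
  uncorrected and visible in any curve within ~3σ of 20 or 80.
* Ages are integer years; fractional ages and variable follow-up intervals
  are not modeled.
* No statistical inference is attached to curves, tails or peaks; the
  percentile tails are descriptive extremes, not significance thresholds.
* Anatomical labeling of ROI centers is a user-supplied lookup; reports
  default to "unlabeled".
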