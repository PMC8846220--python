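# Methods

## The model in brief

`cct` treats progression through the cell cycle as motion of a hidden switching
system observed through extensive molecular quantities (transcript counts of
lumped gene groups). Three levels of description are implemented, from most
abstract to most concrete:

1. **Switching automaton** (`cct.automaton`). The observable state is a point
   `x ∈ R^n` holding the *logarithms* of `n` extensive quantities; the hidden
   state `s` is one of finitely many intrinsic states, each with a growth
   vector `a_s`. Between events the system moves along the ray `x(t) = x0 +
   a_s t` — linear motion in log coordinates is allometric growth, i.e. any two
   quantities co-vary as a power law. Crossing a switch hyperplane
   `f(x) = b + ⟨c, x⟩ = 0` remaps the hidden state without moving `x`; crossing
   the active division hyperplane translates `x` by a vector `d` with strictly
   negative components (ideally all `−log 2`: every extensive quantity halves
   at cytokinesis) and optionally resets the state. Trajectories settle on a
   limit cycle (a reproducing cell cycle), diverge, or stall.

   A limit cycle forces the *cone condition*: the dwell times `λ_i ≥ 0` along
   the visited growth vectors must satisfy `Σ λ_i a_i + d = 0`, i.e. `−d` lies
   in the convex cone of the growth vectors. In general position this requires
   at least as many intrinsic states as embedding dimensions (`m ≥ n`);
   `cone_feasibility` decides the condition as a linear program (HiGHS) and
   returns a witness `λ`.

2. **Two-dimensional switch model** (`cct.kinetics.SwitchModel2D`). The plane
   is spanned by the log-scale aggregate expression of S-phase genes (`x_S`)
   and of G2/M genes (`x_M`). Each coordinate has a three-level trigger —
   2 = synthesis, 1 = passive decay, 0 = active degradation — with per-level
   rates ordered `k_2 > 0 > k_1` and `k_0 < 0` (and `k_0 < k_1` when the
   anchor geometry respects the level semantics; a violation degrades to a
   warning because empirical anchors can order the two decay slopes either
   way). Three switches (synthesis-on when the summed scores fall to `c_min`;
   S-synthesis-off at `S_max`; all-off at `M_max`) and a division trigger at
   `M_e` in state (1,1) produce the canonical state sequence
   (0,0) → (2,2) → (1,2) → (1,1). Free parameters: 4 thresholds + one
   direction per visited state = 8. The model is constructed directly from
   five trajectory anchor points; growth directions are unit vectors of the
   anchor-to-anchor displacements.

3. **Kinetic model** (`cct.kinetics`). Physical time enters through linear
   synthesis/degradation kinetics `dS/dt = kt_S(t) − kd_S(t)·S` (same for `M`)
   with piecewise-constant rates over four transcriptional epochs:

   | epoch | meaning                      | S rates            | M rates               |
   |-------|------------------------------|--------------------|-----------------------|
   | T1    | post-mitotic degradation     | 0, `kd_s` (active) | 0, `kd_m` (active)    |
   | T1s   | synthesis of both programs   | `kt_s`, `kd_s2`    | `kt_m`, `kd_m2`       |
   | T2s   | S off, boosted G2/M          | 0, `kd_s2`         | `p·kt_m`, `kd_m2`     |
   | Tm    | mitosis, no transcription    | 0, `kd_s2`         | 0, `kd_m2`            |

   Circular boundary conditions `S(T) = S_f·S(0)`, `M(T) = M_f·M(0)` (with
   division drops `1 ≤ S_f, M_f ≤ 2`; empirically ~1.7–1.8 rather than the
   ideal 2 because sequencing sampling does not halve every program equally)
   close the cycle and yield the initial state in closed form; every epoch
   border follows analytically. Each constant-rate segment solves to
   `x(t) = kt/kd + (x0 − kt/kd)e^{−kd t}` (or `x0 + kt·t` when `kd = 0`), so
   each log coordinate is monotone within an epoch.

## Identifiability and fitting

The five observable turning points of the trajectory give 10 coordinates. The
13 natural parameter combinations (`kt/kd2` saturation levels, the six
`kd·duration` products, `S_f`, `M_f`, `p`) obey two exact internal relations
(the S- and M-branch ratios of `T2s/T1s` and `Tm/T1s` coincide), leaving 11
independent combinations — confirmed numerically by the rank of the
finite-difference Jacobian of the combination map (two exact zero singular
values). Absolute physical time is not identifiable: jointly rescaling time
and all rates leaves every combination, and the trajectory, unchanged.

Fitting therefore fixes `T1` and `T1s` (conventionally to their pseudotime
fractions) and constrains mitosis to be fast: `T1s/Tm = 10` by default
(`t1s_over_tm`). With those constraints the inverse problem has 10 unknowns
for 10 coordinates and each epoch segment determines one parameter in closed
form (e.g. `kd_s = ln(S0/S1)/T1`, `kd_s2 = ln(S3/S4)/Tm`, `p` from the T2s
segment of `M`). The closed-form inversion initializes a bounded
Levenberg–Marquardt least-squares polish on the log-parameters (sum of squared
log-space distances of the model borders to the observed points, tolerance
1e-8, at most 500 iterations); from the exact start the polish is a no-op and
serves only to absorb marginally inconsistent input. Non-convergence raises
with a residual report.

Noise propagation: the `Tm` segment is short by construction, so additive
jitter on the turning points is amplified into the base decay rates by roughly
the ratio of jitter to the segment's extent. Recovery is unbiased (the
products `kd·duration` are linear in the log-coordinates), and averaging fits
over jitter replicates recovers all combinations to well under 1%.

## Trajectory reconstruction pipeline

Input is a raw genes × cells UMI count matrix. Stages:

1. **First-pass normalization** (scanpy): per-cell scaling to the global
   median total, `ln(1+x)`, top 10,000 most-variable genes, PCA to 30
   components, Euclidean kNN graph with `k = 10` (self excluded).
2. **Neighbor pooling**: raw counts of each cell are summed with its `k`
   neighbors' counts, compensating technical dropout. The *initial* per-cell
   totals are kept — pooling smears the division jump, so all library-size
   reasoning below uses the pre-pooling totals.
3. **Closed principal curve** in the PCA space of the pooled, initially
   normalized matrix (see below), with per-cell partition to the nearest node
   and pseudotime in edge units.
4. **Trajectory-based renormalization.** Global library-size normalization
   would erase the biological rise of total RNA along the cycle and its
   halving at division, so each cell is instead scaled to the *local* median:
   the partition with anomalously wide totals (IQR > 3× the median partition
   IQR) marks the division moment, mixing the largest pre-division and
   smallest post-division libraries; a 1-D 2-means on its log-totals finds the
   antimode and the two halves are reassigned to the flanking partitions.
   Partition medians of the totals are then interpolated cyclically
   (piecewise-linear by default, periodic cubic spline optionally) as a
   function of pseudotime — each partition sits at the circular mean of its
   cells' pseudotimes, which keeps the interpolation independent of the
   arbitrary node indexing of a closed curve — and every cell is scaled so its
   total matches the smoothed median at its pseudotime. Scaling is per-column,
   so within-cell gene proportions are untouched. The rescaled counts are
   re-pooled, log-transformed and variable genes re-selected.
5. **Second-pass curve, pseudotime, curvature.** A new closed curve is fitted
   to the renormalized embedding. The root is placed at the largest drop in
   per-node median totals (the division gap) and the direction chosen so the
   initial totals increase with pseudotime (rank correlation; if both
   orientations correlate negatively the larger one wins with a warning).
   Node coordinates are interpolated per dimension by cubic splines in the
   edge-unit parameter (periodic for closed curves) and the curvature at a
   node is the Euclidean norm of the second-derivative vector — the nodes of
   an elastic curve are approximately equispaced, so the natural parameter
   stands in for arc length; a speed-normalized (Frenet-style) variant is
   available via `normalize_speed`. Curvature peaks (local maxima with
   prominence ≥ 25% of the maximum, at most 5, seam-aware for closed curves)
   segment pseudotime into transcriptional epochs: four segments map onto
   T1/T1s/T2s/Tm, five onto an extra early-G1 segment.
6. **Scores and markers.** A phase score is the per-cell mean of log-scale
   marker expression (the log of a geometric mean); the packaged default S and
   G2/M marker lists are the standard scoring sets. Epoch markers are ranked
   by the difference of mean log expression inside vs outside the epoch (log
   fold change), after a total-variance floor.
7. **Effective rank**: the number of leading singular values within a 10-fold
   conditioning bound — used, e.g., to show that the five epoch directions of
   a cyclically closing trajectory span one dimension fewer than their count.

## Elastic principal curves

The principal-curve engine is self-contained (`cct.principal_curve`): a
polyline with `q` nodes minimizing

    U = MSE/N + stretch · Σ_edges ‖y_i − y_j‖² + bend · Σ ‖y_{i−1} − 2y_i + y_{i+1}‖²

by alternating nearest-node partition and an exact per-coordinate linear
solve; both half-steps decrease `U`, so fitting is monotone (asserted in the
tests). Defaults `stretch = 0.005`, `bend = 0.05` keep nodes of a dense
noiseless circle within ~1–2% of the generating radius at `q = 30` while
regularizing sparse regions. Closed curves initialize on the PCA ellipse of
the data (deterministic). An open curve is obtained by fitting a closed curve
with `q+1` nodes, deleting the least-populated node (for cyclic data: the
division gap) and refitting the remaining `q`-node path without the closing
edge — the delete-then-refit recipe is ambiguous about final node counts, so
this implementation fixes it at exactly `q`.

## Doubling time from trajectory length

Fast-cycling cells lack the time to degrade mitotic transcripts during G1, so
the trajectory contracts. `principal_circle_length` fits a closed curve
(default `q = 30`) in the plane of the two phase scores, each divided by its
maximum, and reports the polyline length `LP`; `regress_doubling_time` is OLS
of doubling time (hours) on `LP` with explicit, user-supplied outlier
exclusion (matching how outliers were identified by inspection in the
original analysis) plus an optional automated flag for externally studentized
residuals `|t| > 3` (statsmodels). Excluded records still receive
predictions. Because of the internal max-scaling, `LP` is invariant to a joint
rescaling of both scores and to cell order; shrinking the cycle's excursion
shrinks `LP` proportionally.

## Synthetic data

`cct.synthetic` generates the structure the framework assumes, so every stage
is testable without downloads: cells uniform in physical time on the analytic
kinetic cycle; four 50-gene epoch programs whose log-expression ramps 0→1
across their epoch and decays across the next (a piecewise-linear log
trajectory with switch points exactly at the epoch borders, the mitosis
program decaying after the division seam); 800 background genes; expected
totals rising as `drop^phase` (drop 1.8) from a 2,000-count baseline and
halving-by-1.8 at the seam; negative-binomial sampling with dispersion 0.1
(`var = μ + 0.1 μ²`; Poisson optional) and optional dropout. Everything is
deterministic given the seed. The truth table (per-cell phase, epoch,
expected totals) and the planted switch phases score pseudotime recovery,
curvature-peak localization and division-drop recovery.

The baseline kinetic parameter set (`default_params`) is a *reconstruction*,
not a fit to data: epoch durations 1:1:1:0.1 (mitosis 10× shorter than T1s,
`T2s/T1s = 1`), a 2.5-fold G2/M boost, division drops 1.8, active
post-division degradation ~3× the base decay. It was chosen once, at design
time, to reproduce the qualitative trajectory regimes the kinetic model is
known for: a broad circular loop in the score plane at baseline, a negative
S/G2M score correlation when T1 and T1s are sharply shortened (×0.05, the
documented default of the perturbation experiment — mimicking embryonic-like
cycles with a minimal G1), and a correlation above baseline when T1 and T2s
are shortened instead. Trajectory clouds add independent Laplace noise
(default scale 0.05 log units) to the log coordinates.

What the generator does *not* emulate: batch effects, doublets, ambient RNA,
mitochondrial content, non-cycling subpopulations, or smooth gene-specific
kinetics beyond the four-program ramp structure. Passing the synthetic
recovery tests therefore demonstrates correctness of the algorithms under the
model's own assumptions, not robustness to every artifact of real droplet
data.

## Numerical choices

* Event detection: exact ray–hyperplane intersection `t* = −f(x)/⟨c, a⟩`,
  accepted only for `t* > 1e-12` so the plane just crossed cannot refire;
  simultaneous crossings (non-general position) resolve to the smallest plane
  index with a warning; divergence proxy `|x_i| > 1e6` log units; limit-cycle
  detection compares post-division positions over a 3-division window at
  tolerance 1e-8, probing periods 1–3 (the constructed 2D model's return map
  contracts by only ~0.82 per division, so classification may need 150–250
  divisions).
* Natural logarithms everywhere; the division shift is `−log 2` per coordinate
  by default and exposed (`division_shift`) for other halving conventions.
* Closed-form kinetic segments require `kd_s2, kd_m2 > 0`; a vanishing
  closure denominator (below 1e-12) raises "non-closing cycle".
* Degenerate inputs raise early: all-zero cells, empty marker intersections,
  constant scores, coincident turning points, fewer than 3 partitions.
* All stochastic components take a seed (`numpy.random.default_rng`); equal
  seeds give bit-identical outputs.

## Problem sizes

The default study conditions are 2,000 cells × 1,000 genes for the synthetic
pipeline runs, 1,000 random draws for the analytic-accuracy and cone-theorem
sweeps, 100 jitter replicates for recovery, and 3,000-cell score clouds for
the perturbation experiments; these sizes make every reported quantity stable
to the third digit while keeping a full run in minutes on one core.

## Known limitations

* The switch-model construction assumes anchors in general position; anchor
  sets whose decay segments are nearly parallel can violate the intended
  `k_0 < k_1` level ordering (warned, not fatal).
* Curvature-based segmentation can report a spurious fifth peak on noisy data
  (the prominence rule is a fixed 25%); epoch labels beyond five segments fall
  back to neutral names.
* The doubling-time regression is a two-parameter OLS on few datasets; it
  transfers across systems only insofar as the score scaling is comparable.
* The open-curve fitter assumes the data's gap is the least-populated node of
  the closed initialization, which fails if the gap is not the sparsest
  region.
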