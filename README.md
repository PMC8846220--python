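# cct — cell cycle trajectories as sequences of switches

`cct` is a toolkit for researchers analyzing proliferating cell populations in
single-cell RNA-seq snapshots. In such data the dominant axis of variation is
often the cell cycle itself: cells trace a closed loop (the cell cycle
trajectory) through transcriptome space, growing in total RNA content and
abruptly halving at division. The package models that loop as a **switching
dynamical system** and provides the matching data-analysis pipeline.

## The models

**Switching automaton.** The observable state is `x ∈ R^n`, the logarithms of
`n` extensive quantities (e.g. lumped transcript counts of gene programs); a
hidden intrinsic state `s` selects a growth vector `a_s`, so between events
the motion `x(t) = x0 + a_s t` is linear in log coordinates (allometric
growth). Switch hyperplanes `b + ⟨c, x⟩ = 0` remap the hidden state; the
division hyperplane triggers a translation by `d` (ideally `(−log 2, …)`,
halving every quantity). A limit cycle requires the cone condition
`Σ λ_i a_i + d = 0` with dwell times `λ_i ≥ 0` — in general position this
forces at least as many intrinsic states as embedding dimensions (`m ≥ n`),
and the package checks it by linear programming.

**Kinetic model.** In the plane of S-phase and G2/M aggregate signals the
dynamics follow `dS/dt = kt_S(t) − kd_S(t)·S` (same for `M`) with
piecewise-constant rates over four transcriptional epochs — post-mitotic
degradation (T1), joint synthesis (T1s), S-off with a `p`-fold G2/M boost
(T2s), and silent mitosis (Tm) — closed by division drops
`S(T) = S_f·S(0)`, `M(T) = M_f·M(0)`. The model is fully analytic: the
cycle-consistent initial state and all epoch borders have closed forms, 11
parameter combinations are identifiable from the five observable turning
points, and fitting is exact given the standard constraints (fixed `T1`,
`T1s`, fast mitosis `T1s/Tm = 10`).

**Pipeline.** From a raw genes × cells count matrix: kNN pooling of counts,
trajectory-based library-size normalization (cells are scaled to the local
median total along the cycle, preserving the rise-and-halve pattern that
global normalization erases), closed elastic principal curve, pseudotime,
curvature-peak segmentation into transcriptional epochs, phase scores, epoch
marker ranking, and an effective-rank dimensionality estimate. Doubling time
is predicted by OLS from the length of the principal circle in the max-scaled
score plane.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from cct import (TurningPoints, build_2d_automaton, classify_asymptotics,
                 fit_turning_points, identifiable_combinations,
                 simulate_noisy_trajectory)
from cct.pipeline import run_cct_pipeline
from cct.synthetic import SynthConfig, default_params, generate_cct_counts

# fit the kinetic model to the five turning points of a trajectory
params = default_params()
tp = TurningPoints.from_params(params)
fit = fit_turning_points(tp, t1=1.0, t1s=1.0, t1s_over_tm=10.0)
print(f"T2s/T1s = {fit.params.t2s / fit.params.t1s:.3f}")
print(f"G2/M boost p = {fit.params.p:.3f}")
print(f"independent combinations = {identifiable_combinations(fit.params)['count']}")

# build the 2D switch automaton from the same anchors and find its limit cycle
model, spec = build_2d_automaton(tp)
res = classify_asymptotics(spec, tp.points[4] + spec.division_shift, (0, 0),
                           n_divisions=250)
print(f"free parameters = {model.n_free_parameters}; cycle = {res.cycle_states}")

# epoch perturbation: a sharply shortened G1 flips the score correlation
short = params.with_scaled_durations(t1=0.05, t1s=0.05)
df = simulate_noisy_trajectory(short, 3000, noise_scale=0.05, seed=1)
print(f"score correlation after shortening T1,T1s = "
      f"{np.corrcoef(df.S_score, df.M_score)[0, 1]:+.3f}")

# reconstruct the trajectory from synthetic counts and score the recovery
ds = generate_cct_counts(SynthConfig(seed=0))
gene_sets = {"S": [f"T1s_g{i:03d}" for i in range(50)],
             "G2M": [f"T2s_g{i:03d}" for i in range(50)]}
out = run_cct_pipeline(ds.counts, gene_sets=gene_sets, q=50, seed=0)
rho = spearmanr(out.pseudotime, ds.truth.phase).statistic
print(f"pseudotime vs true phase: Spearman rho = {rho:.3f}")
print(f"division drop recovered = {out.normalization.division_drop_ratio:.2f}"
      f" (planted 1.8)")
```

Output:

```
T2s/T1s = 1.000
G2/M boost p = 2.500
independent combinations = 11
free parameters = 8; cycle = ((0, 0), (2, 2), (1, 2), (1, 1))
score correlation after shortening T1,T1s = -0.170
pseudotime vs true phase: Spearman rho = 0.936
division drop recovered = 1.72 (planted 1.8)
```

Reading the numbers: the fitted epoch-duration ratio and the 2.5-fold G2/M
transcriptional boost are recovered exactly from noiseless turning points, the
automaton constructed from the same five anchors cycles through its four
intrinsic states in the canonical order with 8 free parameters, sharply
shortening the G1-related epochs produces the anti-correlated score pattern
characteristic of embryonic-like cycles, and the full pipeline recovers the
planted cyclic ordering (ρ = 0.94) and the 1.8-fold division drop from raw
synthetic counts.

## Command line

```bash
cct synth counts --seed 0 --out data/            # synthetic counts + truth table
cct pipeline run --counts data/matrix.mtx --genes data/genes.tsv \
    --cells data/barcodes.tsv --q 50 --seed 0 --out results/
cct kinetics fit --turning-points tp.csv --out fit.json
cct kinetics perturb --fit fit.json --scale-t1 0.05 --scale-t1s 0.05 --out cloud.csv
cct automaton simulate --spec spec.json --x0 0,0 --s0 0 --max-divisions 50 --out traj.csv
cct doubling-time --scores-dir scores/ --meta meta.csv --exclude CHLA10,SCC25 --out report.json
```

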