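"""Synthetic single-cell count data with a planted cell cycle trajectory.

The generator emulates the statistical structure the trajectory framework
assumes: cells placed uniformly in physical time along the analytic kinetic
cycle; four epoch-specific gene programs whose log-expression rises linearly
during their epoch and relaxes afterwards (giving a piecewise-linear log-space
trajectory with sharp turns at the epoch switches); total counts rising
multiplicatively along the cycle and dropping by the configured division
factor at the cycle seam; counts drawn Poisson or negative-binomial with
optional dropout.  The accompanying truth table (per-cell phase, epoch,
expected totals) scores every pipeline stage without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import EPOCHS, KineticParams, RateSchedule, TurningPoints, epoch_boundaries
from .pipeline import CountMatrix

__all__ = ["SynthConfig", "SyntheticDataset", "generate_cct_counts", "generate_turning_points",
           "epoch_direction_vectors", "default_params"]


def default_params() -> KineticParams:
    """Baseline kinetic parameters used as the generating trajectory.

    Epoch durations in arbitrary time units with mitosis 10x shorter than
    T1s; active post-division degradation ~5x the base decay; a 2.5-fold G2/M
    synthesis boost; division drops of 1.8 (the empirically typical 1.7-1.8
    range for UMI totals rather than the ideal 2.0).
    """
    return KineticParams(
        kt_s=10.0, kt_m=8.0,
        kd_s=1.5, kd_m=1.5,
        kd_s2=0.5, kd_m2=0.45,
        p=2.5,
        s_f=1.8, m_f=1.8,
        t1=1.0, t1s=1.0, t2s=1.0, tm=0.1,
    )


@dataclass
class SynthConfig:
    """Configuration of the synthetic count generator.

    Defaults: 2,000 cells x 1,000 genes; four epoch programs of 50 genes each
    plus 800 background genes; negative binomial counts with dispersion 0.1;
    division drop 1.8 on the totals.
    """

    n_cells: int = 2000
    n_genes: int = 1000
    params: KineticParams = field(default_factory=default_params)
    genes_per_program: int = 50
    program_amplitude: float = 1.2  # peak log-expression lift of a program gene
    mean_total: float = 2000.0  # expected library size at cycle start
    division_drop: float = 1.8  # fold rise of totals over one cycle (= drop at division)
    distribution: str = "nb"  # "nb" or "poisson"
    dispersion: float = 0.1  # NB: var = mu + dispersion * mu^2
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if self.distribution not in ("nb", "poisson"):
            raise ValueError("distribution must be 'nb' or 'poisson'")
        if self.distribution == "nb" and self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_cells <= 0 or self.n_genes <= 0 or self.mean_total <= 0:
            raise ValueError("sizes must be positive")
        if 4 * self.genes_per_program > self.n_genes:
            raise ValueError("program genes exceed the gene count")


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    truth: pd.DataFrame  # cell_id, time, phase, epoch, expected_total
    switch_phases: np.ndarray  # phase fractions of the three interior epoch switches
    program_genes: dict[str, np.ndarray]


def _program_profiles(phase: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """(4, n_cells) triangular log-space activation per epoch program.

    Program j ramps linearly 0 -> 1 across epoch j and decays linearly back to
    0 across the following epoch (cyclically), producing a piecewise-linear
    log trajectory with switch points exactly at the epoch borders.
    """
    profiles = np.zeros((4, phase.size))
    starts = edges[:-1]
    ends = edges[1:]
    for j in range(4):
        up = (phase >= starts[j]) & (phase < ends[j])
        profiles[j, up] = (phase[up] - starts[j]) / (ends[j] - starts[j])
        nxt = (j + 1) % 4  # the Tm program decays after the division seam, in T1
        s, e = starts[nxt], ends[nxt]
        down = (phase >= s) & (phase < e)
        profiles[j, down] = 1.0 - (phase[down] - s) / (e - s)
    return profiles


def generate_cct_counts(config: SynthConfig) -> SyntheticDataset:
    """Generate a count matrix whose dominant variation is cyclic progression.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    params = config.params
    T = params.period
    t = np.sort(rng.uniform(0.0, T, size=config.n_cells))
    phase = t / T

    sched = RateSchedule.from_params(params)
    edges_t = np.concatenate([[0.0], np.cumsum(sched.durations)])
    edges = edges_t / T
    epoch_idx = np.clip(np.searchsorted(edges, phase, side="right") - 1, 0, 3)

    # expected totals rise by the division drop factor over one cycle
    expected_total = config.mean_total * config.division_drop ** phase

    gpp = config.genes_per_program
    n_prog = 4 * gpp
    profiles = _program_profiles(phase, edges)  # (4, n_cells)

    log_rel = np.zeros((config.n_genes, config.n_cells))
    program_genes: dict[str, np.ndarray] = {}
    base = rng.lognormal(mean=0.0, sigma=0.5, size=config.n_genes)
    for j, name in enumerate(EPOCHS):
        rows = np.arange(j * gpp, (j + 1) * gpp)
        program_genes[name] = rows
        log_rel[rows] = config.program_amplitude * profiles[j][None, :]
    rel = base[:, None] * np.exp(log_rel)
    # scale columns so each cell's expected library size follows the planted totals
    mu = rel / rel.sum(axis=0, keepdims=True) * expected_total[None, :]

    if config.distribution == "poisson":
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu * config.dispersion)
        counts = rng.poisson(lam)
    if config.dropout > 0:
        counts = counts * (rng.random(counts.shape) >= config.dropout)

    cell_ids = np.array([f"cell_{i:04d}" for i in range(config.n_cells)], dtype=object)
    gene_ids = np.array(
        [f"{EPOCHS[g // gpp]}_g{g % gpp:03d}" if g < n_prog else f"bg_g{g - n_prog:03d}"
         for g in range(config.n_genes)],
        dtype=object,
    )
    cm = CountMatrix(counts.astype(np.int64), gene_ids, cell_ids)
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids.astype(str),
            "time": t,
            "phase": phase,
            "epoch": [EPOCHS[k] for k in epoch_idx],
            "expected_total": expected_total,
        }
    )
    return SyntheticDataset(cm, truth, edges[1:4].copy(), program_genes)


def expected_log_expression(config: SynthConfig, phases: np.ndarray) -> np.ndarray:
    """Noiseless log expected expression per gene at given phase fractions.

    (n_genes, len(phases)); the deterministic part of the generator, before
    count sampling.  Uses a fixed gene baseline (seeded by the config) so that
    repeated calls agree with :func:`generate_cct_counts` up to sampling noise.
    """
    phases = np.asarray(phases, dtype=float)
    rng = np.random.default_rng(config.seed)
    _ = rng.uniform(0.0, config.params.period, size=config.n_cells)  # keep stream aligned
    sched = RateSchedule.from_params(config.params)
    edges = np.concatenate([[0.0], np.cumsum(sched.durations)]) / config.params.period
    profiles = _program_profiles(phases, edges)
    gpp = config.genes_per_program
    base = rng.lognormal(mean=0.0, sigma=0.5, size=config.n_genes)
    log_rel = np.zeros((config.n_genes, phases.size))
    for j in range(4):
        log_rel[j * gpp : (j + 1) * gpp] = config.program_amplitude * profiles[j][None, :]
    rel = base[:, None] * np.exp(log_rel)
    total = config.mean_total * config.division_drop ** phases
    mu = rel / rel.sum(axis=0, keepdims=True) * total[None, :]
    return np.log(mu)


def epoch_direction_vectors(config: SynthConfig | None = None) -> np.ndarray:
    """Unit direction vectors of the five planted trajectory segments, (5, n_genes).

    Rows 0-3: log-space movement over each transcriptional epoch; row 4: the
    division jump.  The four epoch movements sum to the negated division jump
    (cyclic closure), so the five vectors span a 4-dimensional subspace of
    gene space even though any four of them are linearly independent.
    """
    config = config or SynthConfig()
    sched = RateSchedule.from_params(config.params)
    edges = np.concatenate([[0.0], np.cumsum(sched.durations)]) / config.params.period
    eps = 1e-9
    phases = np.clip(edges, eps, 1.0 - eps)
    logmu = expected_log_expression(config, phases)
    dirs = [logmu[:, k + 1] - logmu[:, k] for k in range(4)]
    dirs.append(logmu[:, 0] - logmu[:, 4])  # division jump back to the cycle start
    dirs = np.array(dirs)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def generate_turning_points(
    params: KineticParams, jitter: float = 0.0, seed: int = 0, jitter_scale: str = "linear"
) -> TurningPoints:
    """Epoch-boundary turning points in log coordinates, optionally jittered.

    ``jitter`` is the standard deviation of independent Gaussian noise added
    to the epoch-boundary coordinates — on the linear amounts by default, or
    multiplicatively (on the log coordinates) with ``jitter_scale='log'``.
    Deterministic given ``seed``.  Degenerate parameters producing
    (near-)coincident points are rejected.
    """
    bounds = epoch_boundaries(params)
    rng = np.random.default_rng(seed)
    if jitter > 0 and jitter_scale == "linear":
        bounds = bounds + rng.normal(scale=jitter, size=bounds.shape)
        if np.any(bounds <= 0):
            raise ValueError("jitter drove a boundary coordinate non-positive")
    pts = np.log(bounds)
    if jitter > 0 and jitter_scale == "log":
        pts = pts + rng.normal(scale=jitter, size=pts.shape)
    diffs = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(diffs < 1e-9):
        raise ValueError("degenerate parameters: coincident turning points")
    return TurningPoints(pts)
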