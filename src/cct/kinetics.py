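"""Analytically solvable kinetic model of cell cycle transcriptome dynamics.

Two lumped variables are tracked: ``S`` (aggregate expression of S-phase
genes) and ``M`` (aggregate expression of G2/M genes).  Each obeys linear
synthesis/degradation kinetics

    dS/dt = kt_S(t) - kd_S(t) * S,     dM/dt = kt_M(t) - kd_M(t) * M,

with piecewise-constant rates over four transcriptional epochs:

=========  ==================================  =============================
epoch      synthesis (S, M)                    degradation (S, M)
=========  ==================================  =============================
T1         0, 0                                kd_s, kd_m   (active, post-division)
T1s        kt_s, kt_m                          kd_s2, kd_m2 (base decay)
T2s        0, p * kt_m                         kd_s2, kd_m2
Tm         0, 0                                kd_s2, kd_m2
=========  ==================================  =============================

``p > 1`` is the transcriptional boost of G2/M genes after S-phase genes shut
off.  The cycle closes with division drops ``S(T) = S_f S(0)``,
``M(T) = M_f M(0)`` (``T = T1+T1s+T2s+Tm``), which fixes the initial state in
closed form (:func:`initial_state`); all epoch-boundary coordinates follow
analytically (:func:`epoch_boundaries`).  Only 11 combinations of the 13 raw
parameters are identifiable from the five observable turning points of the
trajectory (:func:`identifiable_combinations`); fitting therefore requires
fixing ``T1``, ``T1s`` and one of ``p``, ``T2s/T1s``, ``T1s/Tm``
(:func:`fit_turning_points`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .automaton import AutomatonSpec, Hyperplane, IntrinsicState, SwitchRule

__all__ = [
    "KineticParams",
    "RateSchedule",
    "TurningPoints",
    "SwitchModel2D",
    "FitResult",
    "solve_segment",
    "initial_state",
    "epoch_boundaries",
    "trajectory",
    "identifiable_combinations",
    "fit_turning_points",
    "build_2d_automaton",
    "simulate_noisy_trajectory",
]

EPOCHS = ("T1", "T1s", "T2s", "Tm")


@dataclass(frozen=True)
class KineticParams:
    """Rates, boost, division drops and epoch durations of the kinetic model.

    Units: synthesis rates in amount/time, degradation rates in 1/time,
    durations in time; ``p``, ``s_f``, ``m_f`` dimensionless.  ``kd_s``/``kd_m``
    act during the post-division active-degradation epoch T1; ``kd_s2``/
    ``kd_m2`` are the base decay rates for the rest of the cycle.
    """

    kt_s: float
    kt_m: float
    kd_s: float
    kd_m: float
    kd_s2: float
    kd_m2: float
    p: float
    s_f: float
    m_f: float
    t1: float
    t1s: float
    t2s: float
    tm: float

    def __post_init__(self):
        for name in ("kt_s", "kt_m", "kd_s", "kd_m", "kd_s2", "kd_m2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.p <= 0:
            raise ValueError("boost factor p must be > 0")
        for name in ("t1", "t1s", "t2s", "tm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"duration {name} must be > 0")
        if self.s_f < 1 or self.m_f < 1:
            raise ValueError("division drops s_f, m_f must be >= 1")

    @property
    def period(self) -> float:
        return self.t1 + self.t1s + self.t2s + self.tm

    def with_scaled_durations(
        self, t1: float = 1.0, t1s: float = 1.0, t2s: float = 1.0, tm: float = 1.0
    ) -> "KineticParams":
        """Multiply epoch durations by the given factors (epoch perturbation)."""
        return replace(
            self, t1=self.t1 * t1, t1s=self.t1s * t1s, t2s=self.t2s * t2s, tm=self.tm * tm
        )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, obj: dict) -> "KineticParams":
        return cls(**{k: float(obj[k]) for k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class RateSchedule:
    """Piecewise-constant (kt_s, kd_s, kt_m, kd_m) over the four epochs."""

    durations: tuple[float, float, float, float]
    rates: tuple[tuple[float, float, float, float], ...]

    @classmethod
    def from_params(cls, params: KineticParams) -> "RateSchedule":
        return cls(
            durations=(params.t1, params.t1s, params.t2s, params.tm),
            rates=(
                (0.0, params.kd_s, 0.0, params.kd_m),
                (params.kt_s, params.kd_s2, params.kt_m, params.kd_m2),
                (0.0, params.kd_s2, params.p * params.kt_m, params.kd_m2),
                (0.0, params.kd_s2, 0.0, params.kd_m2),
            ),
        )

    def epoch_at(self, t: float) -> int:
        edges = np.cumsum(self.durations)
        return int(np.searchsorted(edges, t, side="right").clip(0, 3))


def _solve_linear(x0: float, kt: float, kd: float, t) -> np.ndarray | float:
    """Closed-form solution of dx/dt = kt - kd*x from x0 over time(s) t."""
    t = np.asarray(t, dtype=float)
    if kd > 0:
        xinf = kt / kd
        out = xinf + (x0 - xinf) * np.exp(-kd * t)
    else:
        out = x0 + kt * t
    return out if out.ndim else float(out)


def solve_segment(
    s_in: float,
    m_in: float,
    rates: tuple[float, float, float, float],
    duration: float,
    n_samples: int = 0,
):
    """Propagate (S, M) through one constant-rate segment.

    ``rates = (kt_s, kd_s, kt_m, kd_m)``, all >= 0.  Returns
    ``(s_out, m_out)`` or, when ``n_samples > 0``, additionally an
    ``(n_samples, 3)`` array of (t, S, M) sampled uniformly over the segment.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    kt_s, kd_s, kt_m, kd_m = rates
    if min(rates) < 0:
        raise ValueError("rates must be >= 0")
    s_out = _solve_linear(s_in, kt_s, kd_s, duration)
    m_out = _solve_linear(m_in, kt_m, kd_m, duration)
    if n_samples <= 0:
        return float(s_out), float(m_out)
    ts = np.linspace(0.0, duration, n_samples)
    path = np.column_stack(
        [ts, _solve_linear(s_in, kt_s, kd_s, ts), _solve_linear(m_in, kt_m, kd_m, ts)]
    )
    return float(s_out), float(m_out), path


def initial_state(params: KineticParams) -> tuple[float, float]:
    """Cycle-closing initial point ``(S(0), M(0))`` in closed form.

    Derived by propagating through the four epochs and imposing the circular
    boundary conditions ``S(T) = S_f S(0)``, ``M(T) = M_f M(0)``.
    """
    if params.kd_s2 <= 0 or params.kd_m2 <= 0:
        raise ValueError("base decay rates must be > 0 for the closed-form initial state")
    ks2, km2 = params.kd_s2, params.kd_m2
    den_s = params.s_f * math.exp(ks2 * (params.t1s + params.t2s + params.tm)) - math.exp(
        -params.kd_s * params.t1
    )
    den_m = params.m_f * math.exp(km2 * (params.t1s + params.t2s + params.tm)) - math.exp(
        -params.kd_m * params.t1
    )
    if abs(den_s) < 1e-12 or abs(den_m) < 1e-12:
        raise ValueError("non-closing cycle: denominator vanishes")
    s0 = (params.kt_s / ks2) * (math.exp(ks2 * params.t1s) - 1.0) / den_s
    m0 = (
        (params.kt_m / km2)
        * (
            params.p * math.exp(km2 * (params.t1s + params.t2s))
            - (params.p - 1.0) * math.exp(km2 * params.t1s)
            - 1.0
        )
        / den_m
    )
    return s0, m0


def epoch_boundaries(params: KineticParams) -> np.ndarray:
    """The five epoch-border points in linear (S, M) amounts, shape (5, 2).

    Rows: start, end of T1, end of T1s, end of T2s, end of the cycle T.  The
    last row equals ``(S_f * S0, M_f * M0)`` by construction.
    """
    s0, m0 = initial_state(params)
    ks2, km2 = params.kd_s2, params.kd_m2
    s1 = s0 * math.exp(-params.kd_s * params.t1)
    m1 = m0 * math.exp(-params.kd_m * params.t1)
    s2 = (params.kt_s / ks2) * (
        1.0 - (1.0 - ks2 / params.kt_s * s1) * math.exp(-ks2 * params.t1s)
    ) if params.kt_s > 0 else s1 * math.exp(-ks2 * params.t1s)
    m2 = (params.kt_m / km2) * (
        1.0 - (1.0 - km2 / params.kt_m * m1) * math.exp(-km2 * params.t1s)
    ) if params.kt_m > 0 else m1 * math.exp(-km2 * params.t1s)
    s3 = s2 * math.exp(-ks2 * params.t2s)
    pk = params.p * params.kt_m
    m3 = (pk / km2) * (
        1.0 - (1.0 - km2 / pk * m2) * math.exp(-km2 * params.t2s)
    ) if pk > 0 else m2 * math.exp(-km2 * params.t2s)
    s4 = s3 * math.exp(-ks2 * params.tm)
    m4 = m3 * math.exp(-km2 * params.tm)
    return np.array([[s0, m0], [s1, m1], [s2, m2], [s3, m3], [s4, m4]])


def trajectory(params: KineticParams, times: np.ndarray) -> np.ndarray:
    """(S, M) amounts at arbitrary times within [0, T], shape (len(times), 2)."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or np.any(times > params.period * (1 + 1e-12)):
        raise ValueError("times must lie within one cycle [0, T]")
    sched = RateSchedule.from_params(params)
    bounds = epoch_boundaries(params)
    edges = np.concatenate([[0.0], np.cumsum(sched.durations)])
    out = np.empty((times.size, 2))
    for j, t in enumerate(np.atleast_1d(times)):
        k = min(int(np.searchsorted(edges, t, side="right")) - 1, 3)
        dt = t - edges[k]
        kt_s, kd_s, kt_m, kd_m = sched.rates[k]
        out[j, 0] = _solve_linear(bounds[k, 0], kt_s, kd_s, dt)
        out[j, 1] = _solve_linear(bounds[k, 1], kt_m, kd_m, dt)
    return out


@dataclass(frozen=True)
class TurningPoints:
    """Five trajectory anchor points in the (log S-score, log G2M-score) plane.

    Rows follow the cycle: (s0, m0) start, (s1, m1) end of active degradation,
    (s_max, m_s) S-peak, (s_m, m_max) M-peak, (s_t, m_t) end of cycle.
    """

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (5, 2):
            raise ValueError("turning points must be a (5, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("turning points must be finite")
        if np.argmax(pts[:, 0]) != 2:
            raise ValueError("s_max (row 2) must carry the maximal S coordinate")
        if np.argmax(pts[:, 1]) != 3:
            raise ValueError("m_max (row 3) must carry the maximal M coordinate")
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_params(cls, params: KineticParams) -> "TurningPoints":
        return cls(np.log(epoch_boundaries(params)))

    def linear(self) -> np.ndarray:
        """Anchor points in linear amounts."""
        return np.exp(self.points)


_COMBINATION_NAMES = (
    "kt_s/kd_s2",
    "kt_m/kd_m2",
    "kd_s*T1",
    "kd_m*T1",
    "kd_s2*T1s",
    "kd_m2*T1s",
    "kd_s2*T2s",
    "kd_m2*T2s",
    "kd_s2*Tm",
    "kd_m2*Tm",
    "S_f",
    "M_f",
    "p",
)


def identifiable_combinations(params: KineticParams) -> dict:
    """The 13 raw parameter combinations entering the fit, and the independent count.

    The raw combinations obey two exact relations: the ratios
    ``(kd*_2 T2s)/(kd*_2 T1s)`` agree between the S and M branches (both equal
    ``T2s/T1s``), and likewise for ``Tm/T1s``; hence 13 - 2 = 11 independent
    combinations, matching the 10 observable turning-point coordinates plus one
    imposed constraint.
    """
    values = {
        "kt_s/kd_s2": params.kt_s / params.kd_s2,
        "kt_m/kd_m2": params.kt_m / params.kd_m2,
        "kd_s*T1": params.kd_s * params.t1,
        "kd_m*T1": params.kd_m * params.t1,
        "kd_s2*T1s": params.kd_s2 * params.t1s,
        "kd_m2*T1s": params.kd_m2 * params.t1s,
        "kd_s2*T2s": params.kd_s2 * params.t2s,
        "kd_m2*T2s": params.kd_m2 * params.t2s,
        "kd_s2*Tm": params.kd_s2 * params.tm,
        "kd_m2*Tm": params.kd_m2 * params.tm,
        "S_f": params.s_f,
        "M_f": params.m_f,
        "p": params.p,
    }
    n_relations = 2
    return {
        "combinations": values,
        "count": len(values) - n_relations,
        "relation_residuals": (
            values["kd_s2*T2s"] / values["kd_s2*T1s"]
            - values["kd_m2*T2s"] / values["kd_m2*T1s"],
            values["kd_s2*Tm"] / values["kd_s2*T1s"]
            - values["kd_m2*Tm"] / values["kd_m2*T1s"],
        ),
    }


@dataclass(frozen=True)
class FitResult:
    params: KineticParams
    residual: float  # sum of squared log-space distances to the turning points
    n_iter: int


def _invert_turning_points(
    tp: TurningPoints, t1: float, t1s: float, t1s_over_tm: float
) -> KineticParams:
    """Exact closed-form inversion: each epoch segment determines one parameter."""
    P = tp.linear()
    (s0, m0), (s1, m1), (s2, m2), (s3, m3), (s4, m4) = P
    tm = t1s / t1s_over_tm
    kd_s = math.log(s0 / s1) / t1
    kd_m = math.log(m0 / m1) / t1
    kd_s2 = math.log(s3 / s4) / tm
    kd_m2 = math.log(m3 / m4) / tm
    t2s = math.log(s2 / s3) / kd_s2
    es = math.exp(-kd_s2 * t1s)
    em = math.exp(-kd_m2 * t1s)
    kt_s = kd_s2 * (s2 - s1 * es) / (1.0 - es)
    kt_m = kd_m2 * (m2 - m1 * em) / (1.0 - em)
    e2 = math.exp(-kd_m2 * t2s)
    p = kd_m2 * (m3 - m2 * e2) / (kt_m * (1.0 - e2))
    return KineticParams(
        kt_s=kt_s, kt_m=kt_m, kd_s=kd_s, kd_m=kd_m, kd_s2=kd_s2, kd_m2=kd_m2,
        p=p, s_f=s4 / s0, m_f=m4 / m0, t1=t1, t1s=t1s, t2s=t2s, tm=tm,
    )


def fit_turning_points(
    tp: TurningPoints,
    t1: float = 1.0,
    t1s: float = 1.0,
    t1s_over_tm: float = 10.0,
    refine: bool = True,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> FitResult:
    """Fit the kinetic model so its epoch boundaries pass through the turning points.

    ``T1`` and ``T1s`` are fixed (the trajectory alone cannot identify absolute
    physical time), and mitosis is constrained to be fast relative to T1s via
    ``t1s_over_tm`` (default: mitosis 10x shorter).  The five observed points
    give ten coordinates and the free quantities number ten, so the direct
    inversion already interpolates; a bounded least-squares polish on the
    log-parameters follows and guards against marginally inconsistent input.

    Raises a ``ValueError`` with a residual report when no parameter vector
    with positive rates reproduces the points (non-convergence).
    """
    if t1 <= 0 or t1s <= 0 or t1s_over_tm <= 0:
        raise ValueError("t1, t1s and t1s_over_tm must be > 0")
    try:
        params0 = _invert_turning_points(tp, t1, t1s, t1s_over_tm)
    except (ValueError, ZeroDivisionError) as exc:
        raise ValueError(f"turning points are not consistent with the rate-level schedule: {exc}")

    target = tp.points.ravel()

    free = ("kt_s", "kt_m", "kd_s", "kd_m", "kd_s2", "kd_m2", "p", "s_f", "m_f", "t2s")

    def unpack(theta: np.ndarray) -> KineticParams:
        vals = dict(zip(free, np.exp(theta)))
        return replace(params0, **vals)

    def resid(theta: np.ndarray) -> np.ndarray:
        try:
            return np.log(epoch_boundaries(unpack(theta))).ravel() - target
        except (ValueError, OverflowError):
            return np.full(10, 1e6)

    theta0 = np.log([getattr(params0, k) for k in free])
    n_iter = 0
    params = params0
    if refine:
        sol = least_squares(
            resid, theta0, method="lm", xtol=tol, ftol=tol, gtol=tol, max_nfev=max_iter * 10
        )
        n_iter = sol.nfev
        params = unpack(sol.x)
    residual = float(np.sum(resid(np.log([getattr(params, k) for k in free])) ** 2))
    if not np.isfinite(residual) or residual > 1e-3 * np.sum(target**2):
        raise ValueError(
            f"fit did not converge: residual sum of squares {residual:.3e} over 10 coordinates"
        )
    return FitResult(params, residual, n_iter)


# ---------------------------------------------------------------------------
# 2D piecewise-linear switch model constructed from trajectory anchors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchModel2D:
    """Two-trigger, three-level switch model in the (log S, log M) plane.

    Trigger levels: 2 = synthesis, 1 = passive decay, 0 = active degradation.
    The growth vector in state (i, j) is ``(k_s[i], k_m[j])``.  Thresholds:
    ``c_min`` triggers synthesis when the summed scores fall to it, ``s_max``
    shuts off S-gene synthesis, ``m_max`` shuts off all transcription, and
    ``m_e`` (crossed downward in state (1, 1)) triggers division.
    """

    c_min: float
    s_max: float
    m_max: float
    m_e: float
    k_s: tuple[float, float, float]  # levels 0, 1, 2
    k_m: tuple[float, float, float]
    division_shift: float = math.log(2.0)

    def __post_init__(self):
        for name, (k0, k1, k2) in (("k_s", self.k_s), ("k_m", self.k_m)):
            if not (k2 > 0 > k1 and k0 < 0):
                raise ValueError(f"{name} must satisfy k2 > 0 > k1 and k0 < 0")
            if not k0 < k1:
                warnings.warn(
                    f"{name}: active-degradation rate is not below the passive decay rate "
                    f"(k0={k0:.3g}, k1={k1:.3g}); anchor geometry violates the level ordering",
                    RuntimeWarning,
                    stacklevel=2,
                )
        if self.c_min >= self.s_max:
            raise ValueError("constraint violated: c_min must be < S_max")
        if self.m_e >= self.m_max:
            raise ValueError("constraint violated: M_e must be < M_max")

    @property
    def n_free_parameters(self) -> int:
        """Free parameters: 4 thresholds + one direction per visited state (4)."""
        n_thresholds = 4
        n_visited_states = len(self.cycle_states())
        return n_thresholds + n_visited_states

    @staticmethod
    def cycle_states() -> tuple[tuple[int, int], ...]:
        """The predefined order of states along the cell cycle."""
        return ((0, 0), (2, 2), (1, 2), (1, 1))

    def to_automaton(self) -> AutomatonSpec:
        states = [
            IntrinsicState((i, j), np.array([self.k_s[i], self.k_m[j]]))
            for i in range(3)
            for j in range(3)
        ]
        labels = [st.label for st in states]
        switches = [
            # g1: sum of scores falls to c_min -> synthesis of both
            SwitchRule(
                Hyperplane(-self.c_min, np.array([1.0, 1.0])),
                {l: (2, 2) for l in labels},
            ),
            # g2: S reaches S_max -> S synthesis off
            SwitchRule(
                Hyperplane(-self.s_max, np.array([1.0, 0.0])),
                {(i, j): ((1, j) if i == 2 else (i, j)) for i, j in labels},
            ),
            # g3: M reaches M_max -> all transcription off
            SwitchRule(
                Hyperplane(-self.m_max, np.array([0.0, 1.0])),
                {l: (1, 1) for l in labels},
            ),
        ]
        division = {(1, 1): Hyperplane(self.m_e, np.array([0.0, -1.0]))}
        d = -self.division_shift
        return AutomatonSpec(
            dimension=2,
            states=states,
            switches=switches,
            division=division,
            division_shift=np.array([d, d]),
            post_division_state=(0, 0),
        )


def build_2d_automaton(
    tp: TurningPoints, division_shift: float = math.log(2.0)
) -> tuple[SwitchModel2D, AutomatonSpec]:
    """Construct the 2D switch model from five trajectory anchors.

    Anchors (log coordinates, ordered along the cycle): start 0, B' (end of
    active degradation; by construction the point with the minimal summed
    scores), C (S-peak), D (M-peak), E (end of cycle / division).  Thresholds
    are read off the anchors and each visited state's growth direction is the
    unit vector of the corresponding segment's displacement.
    """
    x0, b, c, d_pt, e = tp.points
    k2 = (c - b) / np.linalg.norm(c - b)
    k1_s = (d_pt[0] - c[0]) / np.linalg.norm(d_pt - c)
    k1_m = (e[1] - d_pt[1]) / np.linalg.norm(e - d_pt)
    k0 = (b - x0) / np.linalg.norm(b - x0)
    model = SwitchModel2D(
        c_min=float(b[0] + b[1]),
        s_max=float(c[0]),
        m_max=float(d_pt[1]),
        m_e=float(e[1]),
        k_s=(float(k0[0]), float(k1_s), float(k2[0])),
        k_m=(float(k0[1]), float(k1_m), float(k2[1])),
        division_shift=division_shift,
    )
    return model, model.to_automaton()


def simulate_noisy_trajectory(
    params: KineticParams,
    n_cells: int,
    noise_scale: float = 0.05,
    seed: int | np.random.Generator = 0,
):
    """Sample a cell cloud around the closed analytic trajectory.

    Cells are placed uniformly in physical time along one cycle; the log-scale
    (S, M) coordinates receive independent Laplace noise of the given scale.
    Returns a DataFrame with cell_id, time, epoch, S_score, M_score.
    """
    import pandas as pd

    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = rng.uniform(0.0, params.period, size=n_cells)
    sm = trajectory(params, t)
    logsm = np.log(sm)
    if noise_scale > 0:
        logsm = logsm + rng.laplace(scale=noise_scale, size=logsm.shape)
    sched = RateSchedule.from_params(params)
    edges = np.cumsum(sched.durations)
    epoch_idx = np.searchsorted(edges, t, side="right").clip(0, 3)
    return pd.DataFrame(
        {
            "cell_id": [f"cell_{i}" for i in range(n_cells)],
            "time": t,
            "epoch": [EPOCHS[k] for k in epoch_idx],
            "S_score": logsm[:, 0],
            "M_score": logsm[:, 1],
        }
    )
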