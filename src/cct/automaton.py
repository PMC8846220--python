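"""Hybrid switching automaton with linear growth in log coordinates.

The automaton ``A(x|s)`` carries a continuous position ``x`` (logarithms of
extensive cell quantities, e.g. lumped transcript counts) and a hidden discrete
intrinsic state ``s``.  In state ``s`` the position moves along a ray
``x(t) = x0 + a_s t`` where ``a_s`` is the state's growth vector.  Crossing a
switch hyperplane remaps the intrinsic state (position unchanged); crossing the
active division hyperplane translates the position by a fixed vector ``d`` with
negative components (ideally all ``-log 2``, halving every extensive quantity)
and optionally resets the state.  Trajectories of this system either settle on
a limit cycle (a self-consistent cell cycle), diverge, or stall.

A necessary condition for a limit cycle is that ``-d`` lies in the convex cone
spanned by the growth vectors of the visited states, i.e. nonnegative dwell
times ``lambda_i`` exist with ``sum_i lambda_i a_i + d = 0``.  In general
position this requires at least as many intrinsic states as embedding
dimensions (m >= n).  :func:`cone_feasibility` tests the condition as a linear
program.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Hyperplane",
    "IntrinsicState",
    "SwitchRule",
    "AutomatonSpec",
    "Breakpoint",
    "TrajectoryRecord",
    "AsymptoticsResult",
    "ConeFeasibility",
    "evaluate_side",
    "simulate",
    "classify_asymptotics",
    "cone_feasibility",
    "spec_to_json",
    "spec_from_json",
]

#: minimal positive crossing time; avoids re-triggering the plane just crossed
CROSSING_EPS = 1e-12
#: coordinate magnitude (in log units) beyond which a trajectory is divergent
OVERFLOW_BOUND = 1e6

Label = Hashable


@dataclass(frozen=True)
class Hyperplane:
    """Affine functional ``f(x) = offset + <normal, x>``; ``f = 0`` is the plane."""

    offset: float
    normal: np.ndarray

    def __post_init__(self):
        normal = np.asarray(self.normal, dtype=float)
        if normal.ndim != 1 or not np.any(normal != 0.0):
            raise ValueError("hyperplane normal must be a 1-D vector with a nonzero component")
        object.__setattr__(self, "normal", normal)
        object.__setattr__(self, "offset", float(self.offset))

    @property
    def dimension(self) -> int:
        return self.normal.shape[0]

    def value(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != self.normal.shape:
            raise ValueError(
                f"dimension mismatch: point has shape {x.shape}, plane normal {self.normal.shape}"
            )
        return self.offset + float(self.normal @ x)


def evaluate_side(x: np.ndarray, plane: Hyperplane) -> float:
    """Signed value of the plane functional at ``x``.

    Two points lie on opposite sides of the plane iff the product of their
    values is negative (the segment between them crosses the plane).
    """
    return plane.value(x)


@dataclass(frozen=True)
class IntrinsicState:
    """Discrete hidden state with its growth vector (log-units per unit time).

    Labels are either plain integers or tuples of trigger levels drawn from a
    finite level set such as ``{0, 1, 2}``.
    """

    label: Label
    growth: np.ndarray

    def __post_init__(self):
        growth = np.asarray(self.growth, dtype=float)
        if growth.ndim != 1:
            raise ValueError("growth vector must be 1-D")
        object.__setattr__(self, "growth", growth)


@dataclass(frozen=True)
class SwitchRule:
    """A switch hyperplane together with the state map it induces."""

    plane: Hyperplane
    mapping: Mapping[Label, Label]

    def apply(self, label: Label) -> Label:
        try:
            return self.mapping[label]
        except KeyError as exc:
            raise KeyError(f"switch map is not defined for state {label!r}") from exc


@dataclass(frozen=True)
class AutomatonSpec:
    """Full specification of the switching automaton.

    Parameters
    ----------
    dimension
        Embedding dimension ``n`` of the continuous position.
    states
        The finite intrinsic state set with growth vectors.
    switches
        Switch rules; each map must be total on the state set.
    division
        Per-state division hyperplane (states absent from the mapping have no
        division plane).
    division_shift
        The vector ``d`` added to the position at division; all components
        must be strictly negative.
    post_division_state
        State after division, or ``None`` to keep the current state.
    """

    dimension: int
    states: Sequence[IntrinsicState]
    switches: Sequence[SwitchRule]
    division: Mapping[Label, Hyperplane]
    division_shift: np.ndarray
    post_division_state: Label | None = None

    def __post_init__(self):
        d = np.asarray(self.division_shift, dtype=float)
        if d.shape != (self.dimension,):
            raise ValueError("division shift dimension mismatch")
        if not np.all(d < 0):
            raise ValueError("division shift must have strictly negative components")
        object.__setattr__(self, "division_shift", d)
        labels = [st.label for st in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate state labels")
        for st in self.states:
            if st.growth.shape != (self.dimension,):
                raise ValueError(f"growth vector of state {st.label!r} has wrong dimension")
        for i, sw in enumerate(self.switches):
            if sw.plane.dimension != self.dimension:
                raise ValueError(f"switch plane {i} has wrong dimension")
            missing = set(labels) - set(sw.mapping)
            if missing:
                raise ValueError(f"switch map {i} is not total; missing {sorted(map(str, missing))}")
            bad = [l for l in labels if sw.mapping[l] not in set(labels)]
            if bad:
                raise ValueError(f"switch map {i} leaves the state set from {bad!r}")
        for lbl, plane in self.division.items():
            if lbl not in set(labels):
                raise ValueError(f"division plane attached to unknown state {lbl!r}")
            if plane.dimension != self.dimension:
                raise ValueError(f"division plane of state {lbl!r} has wrong dimension")
        if self.post_division_state is not None and self.post_division_state not in set(labels):
            raise ValueError("post-division state is not in the state set")

    def state(self, label: Label) -> IntrinsicState:
        for st in self.states:
            if st.label == label:
                return st
        raise KeyError(f"unknown state {label!r}")

    def birth_plane(self, label: Label) -> Hyperplane:
        """Division plane of ``label`` translated by ``d`` (where newborns sit)."""
        plane = self.division[label]
        # f(x - d) = offset + <c, x> - <c, d>: shift the offset
        return Hyperplane(plane.offset + float(plane.normal @ self.division_shift), plane.normal)


@dataclass(frozen=True)
class Breakpoint:
    time: float
    x: np.ndarray
    state: Label
    event: str  # start | switch | division | end


@dataclass
class TrajectoryRecord:
    """Piecewise-linear trajectory: ordered event breakpoints plus termination tag."""

    breakpoints: list[Breakpoint]
    termination: str  # max_events | max_time | max_divisions | divergent | stalled

    def times(self) -> np.ndarray:
        return np.array([b.time for b in self.breakpoints])

    def positions(self) -> np.ndarray:
        return np.array([b.x for b in self.breakpoints])

    def division_indices(self) -> list[int]:
        return [i for i, b in enumerate(self.breakpoints) if b.event == "division"]

    def post_division_positions(self) -> np.ndarray:
        idx = self.division_indices()
        n = self.breakpoints[0].x.shape[0]
        if not idx:
            return np.zeros((0, n))
        return np.array([self.breakpoints[i].x for i in idx])

    def states_between_divisions(self) -> list[Label]:
        """Intrinsic states visited between the last two division events, in order."""
        idx = self.division_indices()
        if len(idx) < 2:
            raise ValueError("need at least two divisions")
        seen: list[Label] = []
        for b in self.breakpoints[idx[-2] : idx[-1]]:
            if not seen or seen[-1] != b.state:
                seen.append(b.state)
        return seen

    def to_dataframe(self):
        import pandas as pd

        n = self.breakpoints[0].x.shape[0]
        rows = [
            {"time": b.time, **{f"x{i + 1}": b.x[i] for i in range(n)},
             "state": str(b.state), "event": b.event}
            for b in self.breakpoints
        ]
        return pd.DataFrame(rows)


def _crossing_time(x: np.ndarray, a: np.ndarray, plane: Hyperplane) -> float | None:
    """First time ``t > eps`` at which the ray ``x + a t`` crosses the plane."""
    denom = float(plane.normal @ a)
    if abs(denom) < 1e-300:
        return None
    t = -plane.value(x) / denom
    if t <= CROSSING_EPS:
        return None
    return t


def simulate(
    spec: AutomatonSpec,
    x0: np.ndarray,
    s0: Label,
    max_events: int = 1000,
    max_time: float = np.inf,
    max_divisions: int | None = None,
) -> TrajectoryRecord:
    """Run the automaton from ``(x0, s0)``, recording every event breakpoint.

    Along each ray the earliest crossing among the switch planes and the
    current state's division plane (smallest positive time) fires.  Simultaneous
    crossings (non-general position) resolve to the smallest plane index with a
    warning; the division plane carries the largest index.  Terminates on
    ``max_events``, ``max_time``, ``max_divisions``, coordinate overflow
    (divergent) or absence of any reachable plane (stalled/divergent).
    """
    x = np.asarray(x0, dtype=float).copy()
    if x.shape != (spec.dimension,):
        raise ValueError("x0 dimension mismatch")
    if not np.all(np.isfinite(x)):
        raise ValueError("x0 must be finite")
    state = spec.state(s0).label  # raises for unknown label
    t = 0.0
    bps = [Breakpoint(0.0, x.copy(), state, "start")]
    n_divisions = 0
    termination = "max_events"
    p = len(spec.switches)

    for _ in range(max_events):
        a = spec.state(state).growth
        candidates: list[tuple[float, int, str]] = []
        for i, sw in enumerate(spec.switches):
            tc = _crossing_time(x, a, sw.plane)
            if tc is not None:
                candidates.append((tc, i, "switch"))
        if state in spec.division:
            tc = _crossing_time(x, a, spec.division[state])
            if tc is not None:
                candidates.append((tc, p, "division"))

        if not candidates:
            if not np.any(a != 0.0):
                termination = "stalled"
                bps.append(Breakpoint(t, x.copy(), state, "end"))
                break
            # free flight to infinity: advance to the overflow bound
            with np.errstate(divide="ignore", invalid="ignore"):
                exit_times = (np.sign(a) * OVERFLOW_BOUND - x) / a
            t_exit = float(np.min(exit_times[a != 0.0]))
            if t + t_exit > max_time:
                bps.append(Breakpoint(max_time, x + a * (max_time - t), state, "end"))
                termination = "max_time"
            else:
                bps.append(Breakpoint(t + t_exit, x + a * t_exit, state, "end"))
                termination = "divergent"
            break

        t_hit = min(c[0] for c in candidates)
        tied = [c for c in candidates if c[0] <= t_hit * (1 + 1e-12) + 1e-15]
        if len(tied) > 1:
            warnings.warn(
                "simultaneous plane crossings; resolving to the smallest plane index",
                RuntimeWarning,
                stacklevel=2,
            )
        t_hit, idx, kind = min(tied, key=lambda c: c[1])

        if t + t_hit > max_time:
            bps.append(Breakpoint(max_time, x + a * (max_time - t), state, "end"))
            termination = "max_time"
            break

        x = x + a * t_hit
        t = t + t_hit
        if kind == "switch":
            state = spec.switches[idx].apply(state)
            bps.append(Breakpoint(t, x.copy(), state, "switch"))
        else:
            x = x + spec.division_shift
            if spec.post_division_state is not None:
                state = spec.post_division_state
            bps.append(Breakpoint(t, x.copy(), state, "division"))
            n_divisions += 1
            if max_divisions is not None and n_divisions >= max_divisions:
                termination = "max_divisions"
                break
        if np.any(np.abs(x) > OVERFLOW_BOUND):
            termination = "divergent"
            bps.append(Breakpoint(t, x.copy(), state, "end"))
            break

    return TrajectoryRecord(bps, termination)


@dataclass(frozen=True)
class AsymptoticsResult:
    kind: str  # limit_cycle | divergent | undecided
    period: int | None = None  # divisions per cycle
    cycle_states: tuple[Label, ...] | None = None
    fixed_point: np.ndarray | None = None


def classify_asymptotics(
    spec: AutomatonSpec,
    x0: np.ndarray,
    s0: Label,
    n_divisions: int = 50,
    tol: float = 1e-8,
    window: int = 3,
) -> AsymptoticsResult:
    """Classify the long-run behaviour from the sequence of post-division positions.

    ``limit_cycle`` when the last ``window`` successive post-division positions
    (taken ``period`` divisions apart, period 1..3) agree within ``tol``;
    ``divergent`` when a coordinate overflows or the trajectory escapes every
    plane; otherwise ``undecided``.
    """
    rec = simulate(
        spec, x0, s0,
        max_events=max(1000, 100 * n_divisions),
        max_divisions=n_divisions,
    )
    if rec.termination in ("divergent", "stalled"):
        return AsymptoticsResult("divergent" if rec.termination == "divergent" else "undecided")
    post = rec.post_division_positions()
    for period in (1, 2, 3):
        if len(post) < window + period:
            continue
        deltas = [
            np.linalg.norm(post[-1 - i] - post[-1 - i - period]) for i in range(window)
        ]
        if max(deltas) < tol:
            states = tuple(rec.states_between_divisions()) if len(post) >= 2 else None
            return AsymptoticsResult("limit_cycle", period, states, post[-1].copy())
    return AsymptoticsResult("undecided")


@dataclass(frozen=True)
class ConeFeasibility:
    feasible: bool
    coefficients: np.ndarray | None = None


def cone_feasibility(
    growth_vectors: Sequence[np.ndarray], d: np.ndarray, tol: float = 1e-9
) -> ConeFeasibility:
    """Test whether nonnegative ``lambda`` exist with ``sum_i lambda_i a_i + d = 0``.

    Equivalently, whether ``-d`` belongs to the convex cone of the growth
    vectors.  Solved as a linear feasibility problem (HiGHS); returns one
    witness ``lambda`` when feasible.
    """
    d = np.asarray(d, dtype=float)
    if len(growth_vectors) == 0:
        if np.allclose(d, 0.0):
            return ConeFeasibility(True, np.zeros(0))
        return ConeFeasibility(False)
    A = np.column_stack([np.asarray(v, dtype=float) for v in growth_vectors])
    if A.shape[0] != d.shape[0]:
        raise ValueError("growth vectors and d must share the dimension")
    m = A.shape[1]
    res = linprog(np.zeros(m), A_eq=A, b_eq=-d, bounds=[(0, None)] * m, method="highs")
    if res.status == 0 and res.x is not None:
        lam = np.maximum(res.x, 0.0)
        if np.linalg.norm(A @ lam + d) <= tol * max(1.0, np.linalg.norm(d)):
            return ConeFeasibility(True, lam)
    return ConeFeasibility(False)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _label_to_json(label: Label):
    return list(label) if isinstance(label, tuple) else label


def _label_from_json(obj) -> Label:
    return tuple(obj) if isinstance(obj, list) else obj


def _label_key(label: Label) -> str:
    return json.dumps(_label_to_json(label))


def spec_to_json(spec: AutomatonSpec) -> dict:
    return {
        "n": spec.dimension,
        "states": [
            {"label": _label_to_json(st.label), "a": st.growth.tolist()} for st in spec.states
        ],
        "switches": [
            {
                "b": sw.plane.offset,
                "c": sw.plane.normal.tolist(),
                "map": {_label_key(k): _label_to_json(v) for k, v in sw.mapping.items()},
            }
            for sw in spec.switches
        ],
        "division": [
            {"state": _label_to_json(lbl), "b": pl.offset, "c": pl.normal.tolist()}
            for lbl, pl in spec.division.items()
        ],
        "d": spec.division_shift.tolist(),
        "s_d": None
        if spec.post_division_state is None
        else _label_to_json(spec.post_division_state),
    }


def spec_from_json(obj: dict) -> AutomatonSpec:
    states = [IntrinsicState(_label_from_json(s["label"]), np.array(s["a"])) for s in obj["states"]]
    switches = [
        SwitchRule(
            Hyperplane(sw["b"], np.array(sw["c"])),
            {_label_from_json(json.loads(k)): _label_from_json(v) for k, v in sw["map"].items()},
        )
        for sw in obj["switches"]
    ]
    division = {
        _label_from_json(dv["state"]): Hyperplane(dv["b"], np.array(dv["c"]))
        for dv in obj["division"]
    }
    return AutomatonSpec(
        dimension=int(obj["n"]),
        states=states,
        switches=switches,
        division=division,
        division_shift=np.array(obj["d"]),
        post_division_state=None if obj.get("s_d") is None else _label_from_json(obj["s_d"]),
    )
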