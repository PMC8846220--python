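"""Ready-made example models.

The exact numeric parameters of the two-state, single-trigger toy automata
exhibiting the qualitative switching regimes (a single limit cycle with
divergence elsewhere, two coexisting limit cycles, sensitive dependence on
the birth position) are not published; the specs below are reconstructions
found by a seeded numerical search over random two-state specs and frozen.
They reproduce the qualitative behaviours, not any particular published
trajectory.  Likewise :func:`baseline_kinetic_params` is a plausible
parameterization of the kinetic cell cycle model chosen to reproduce the
published qualitative regimes (T2s/T1s = 1, a 2.5-fold G2/M boost, fast
mitosis, 1.8-fold division drops, and the epoch-shortening correlation
patterns); it is not a fit to any dataset.
"""

from __future__ import annotations

import math

import numpy as np

from .automaton import AutomatonSpec, Hyperplane, IntrinsicState, SwitchRule
from .kinetics import KineticParams

__all__ = [
    "baseline_kinetic_params",
    "toy_single_cycle",
    "toy_two_cycles",
    "toy_sensitive",
]

_LOG2 = math.log(2.0)


def baseline_kinetic_params() -> KineticParams:
    """Baseline kinetic parameter set (synthetic-data generating trajectory)."""
    from .synthetic import default_params

    return default_params()


def _two_state_spec(a0, a1, planes, h, s_d) -> AutomatonSpec:
    """Two states driven by one binary trigger; both switch maps are constant
    (plane 0 turns the trigger on, plane 1 turns it off); a shared horizontal
    division plane x2 = h with shift (-log 2, -log 2)."""
    states = [IntrinsicState(0, np.array(a0)), IntrinsicState(1, np.array(a1))]
    switches = [
        SwitchRule(Hyperplane(b, np.array(c)), {0: target, 1: target})
        for (b, c), target in zip(planes, (1, 0))
    ]
    div_plane = Hyperplane(-h, np.array([0.0, 1.0]))
    return AutomatonSpec(
        dimension=2,
        states=states,
        switches=switches,
        division={0: div_plane, 1: div_plane},
        division_shift=np.array([-_LOG2, -_LOG2]),
        post_division_state=s_d,
    )


def toy_single_cycle() -> tuple[AutomatonSpec, float]:
    """Single limit cycle; birth positions x1 >= 0 diverge instead.

    Returns the spec and the division-plane height h (the birth line sits at
    x2 = h - log 2).  Start states: label 0.
    """
    spec = _two_state_spec(
        a0=[-0.7542157955899813, 0.9342964707947354],
        a1=[0.31552146007702886, -0.14355950722103739],
        planes=[
            (-0.6231573320158952, [0.07288827295282133, 0.9973401123317737]),
            (-0.5783448919059517, [-0.9498537607725102, 0.312694472522811]),
        ],
        h=1.278647729743985,
        s_d=1,
    )
    return spec, 1.278647729743985


def toy_two_cycles() -> tuple[AutomatonSpec, float]:
    """Two coexisting (period-2) limit cycles, selected by the birth position.

    Birth positions x1 <= -2 settle on one cycle, x1 in [-1.5, 0.5] on the
    other; division keeps the intrinsic state.
    """
    spec = _two_state_spec(
        a0=[-0.6959346999241707, 0.7300850487374628],
        a1=[0.2887306393725515, 0.20710820432549837],
        planes=[
            (-1.0596053939549366, [-0.026429866779660114, 0.9996506700552996]),
            (0.9148775111248684, [-0.8014104818026577, -0.5981147378696099]),
        ],
        h=1.5586011000549487,
        s_d=None,
    )
    return spec, 1.5586011000549487


def toy_sensitive() -> tuple[AutomatonSpec, float]:
    """Sensitive dependence: of three nearby birth positions (x1 = -0.5, 0,
    +0.5) the outer two diverge while the middle one reaches the limit cycle."""
    spec = _two_state_spec(
        a0=[-0.7325576223229546, 0.32489244322850763],
        a1=[0.6611050645263679, -0.2462924371824351],
        planes=[
            (-1.1397688814476257, [-0.9539300405027515, -0.30002912829660155]),
            (-1.6738741587897064, [-0.9869681796609531, -0.16091554411163822]),
        ],
        h=1.6290982045505085,
        s_d=1,
    )
    return spec, 1.6290982045505085
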