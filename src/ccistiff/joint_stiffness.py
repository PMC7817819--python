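"""Sagittal-plane joint stiffness assembled from muscle-level quantities.

Joint stiffness is defined as the elastic response of the net joint moment to
a change in joint position at fixed activation:

    K_joint = −∂M_j/∂θ_j,          M_j = Σ_i r_ij · F_T,i

Expanding via the product/chain rules and r_ij = −∂l_MT,i/∂θ_j gives the
per-muscle decomposition implemented here:

    K_mus,i = r_ij²·(∂F_T,i/∂l_MT,i) − (∂r_ij/∂θ_j)·F_T,i
    K_joint = Σ_i K_mus,i

All ingredients are analytic (polynomial geometry, closed-form rigid-tendon
force and slope), so the assembly is exact; the central-difference oracle on
−∂M/∂θ is what the test suite gates it against.  Biarticular muscles
contribute to each spanned DOF independently — the single-DOF partial
derivative carries no cross-joint terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import moment_arm, moment_arm_gradient, mtu_length
from .musculotendon import tendon_force, tendon_force_slope
from .subject import MuscleEntry, SubjectLegModel

__all__ = [
    "StiffnessSeries",
    "joint_moment",
    "muscle_stiffness",
    "stiffness_series",
    "contribution_fractions",
]

N_GRID = 101  # % gait cycle, 0–100 at 1% increments


@dataclass(frozen=True)
class StiffnessSeries:
    """Per-cycle joint stiffness with per-muscle contributions.

    ``k_joint`` and ``m_joint`` are 101-point arrays over the normalized gait
    cycle (N·m/rad and N·m); ``k_mus`` maps muscle name → 101-point array and
    sums exactly to ``k_joint``.
    """

    dof: str
    cycle_index: int
    k_joint: np.ndarray
    k_mus: dict[str, np.ndarray]
    m_joint: np.ndarray

    def __post_init__(self) -> None:
        if self.k_joint.shape != (N_GRID,) or self.m_joint.shape != (N_GRID,):
            raise ValueError("stiffness series must have exactly 101 points")
        total = np.sum(list(self.k_mus.values()), axis=0)
        scale = np.maximum(np.abs(self.k_joint), 1.0)
        if np.max(np.abs(total - self.k_joint) / scale) > 1e-9:
            raise ValueError("k_joint must equal the sum of k_mus contributions")


def _spanning_with_activation(
    leg: SubjectLegModel, activations: dict[str, float | np.ndarray], dof: str
) -> list[tuple[MuscleEntry, np.ndarray]]:
    out = []
    for m in leg.spanning(dof):
        if m.name not in activations:
            raise KeyError(f"no activation provided for spanning muscle {m.name!r}")
        out.append((m, np.asarray(activations[m.name], dtype=float)))
    return out


def joint_moment(
    leg: SubjectLegModel,
    activations: dict[str, float | np.ndarray],
    angles: dict[str, float | np.ndarray],
    dof: str,
):
    """Net muscle moment M_j = Σ r_ij·F_T,i over muscles spanning ``dof`` (N·m)."""
    total = 0.0
    for m, a in _spanning_with_activation(leg, activations, dof):
        l_mt = mtu_length(m.geometry, angles)
        r = moment_arm(m.geometry, angles, dof)
        total = total + r * tendon_force(m.params, a, l_mt)
    return total


def muscle_stiffness(
    leg: SubjectLegModel,
    muscle: str,
    a: float | np.ndarray,
    angles: dict[str, float | np.ndarray],
    dof: str,
):
    """K_mus = r²·∂F_T/∂l_MT − (∂r/∂θ)·F_T for one muscle (N·m/rad)."""
    m = leg.muscle(muscle)
    if not m.geometry.spans(dof):
        raise ValueError(f"{muscle!r} does not span {dof!r}")
    a = np.asarray(a, dtype=float)
    l_mt = mtu_length(m.geometry, angles)
    r = moment_arm(m.geometry, angles, dof)
    dr = moment_arm_gradient(m.geometry, angles, dof)
    return r**2 * tendon_force_slope(m.params, a, l_mt) - dr * tendon_force(
        m.params, a, l_mt
    )


def stiffness_series(
    leg: SubjectLegModel,
    activation_cycles: dict[str, np.ndarray],
    angle_cycles: dict[str, np.ndarray],
    dof: str,
    cycle_index: int = 0,
) -> StiffnessSeries:
    """Assemble one cycle's 101-point stiffness and moment series.

    ``activation_cycles`` maps muscle → 101-point activation; ``angle_cycles``
    maps DOF → 101-point angle (radians).  All series must share the 101-point
    normalized-time grid.
    """
    for name, series in {**activation_cycles, **angle_cycles}.items():
        if np.shape(series) != (N_GRID,):
            raise ValueError(f"series {name!r} must have exactly {N_GRID} points")
    angles = {d: np.asarray(v, dtype=float) for d, v in angle_cycles.items()}
    k_mus: dict[str, np.ndarray] = {}
    m_joint = np.zeros(N_GRID)
    for m in leg.spanning(dof):
        if m.name not in activation_cycles:
            raise KeyError(f"no activation cycle for spanning muscle {m.name!r}")
        a = np.asarray(activation_cycles[m.name], dtype=float)
        k_mus[m.name] = np.asarray(muscle_stiffness(leg, m.name, a, angles, dof))
        l_mt = mtu_length(m.geometry, angles)
        r = moment_arm(m.geometry, angles, dof)
        m_joint = m_joint + r * tendon_force(m.params, a, l_mt)
    if not k_mus:
        raise ValueError(f"no muscle spans {dof!r}")
    k_joint = np.sum(list(k_mus.values()), axis=0)
    return StiffnessSeries(
        dof=dof, cycle_index=cycle_index, k_joint=k_joint, k_mus=k_mus, m_joint=m_joint
    )


def contribution_fractions(series: StiffnessSeries | list[StiffnessSeries]):
    """Mean fractional |K_mus| contribution per muscle (fractions sum to 1).

    Accepts one cycle or a list of cycles; with several cycles the average runs
    over all cycle points.  Used downstream to drop muscles contributing less
    than 2% of joint stiffness on average.
    """
    if isinstance(series, StiffnessSeries):
        series = [series]
    if not series:
        raise ValueError("no stiffness series given")
    muscles = list(series[0].k_mus)
    abs_mus = {m: np.concatenate([np.abs(s.k_mus[m]) for s in series]) for m in muscles}
    denom = np.sum(list(abs_mus.values()), axis=0)
    if np.all(denom == 0):
        raise ValueError("all-zero stiffness: contribution fractions undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = {
            m: float(np.mean(np.where(denom > 0, v / np.where(denom > 0, denom, 1.0), 0.0)))
            for m, v in abs_mus.items()
        }
    total = sum(frac.values())
    return {m: v / total for m, v in frac.items()}
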