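"""Subject model containers: muscles, legs, and the virtual subject.

These types stand in for a calibrated EMG-driven musculoskeletal model: each
muscle carries Hill-type parameters, a polynomial length surrogate, a
functional-role table (FLEX/EXT per joint, DF/PF at the ankle), an EMG scale
factor in (0, 1], and a surface/fine-wire flag; each leg carries one
electromechanical delay shared by all its muscles.

Role consistency is enforced against the agonist-positive moment-arm
convention: a FLEX/DF muscle must have r > 0 at the neutral pose, an EXT/PF
muscle r < 0.  A mismatch is a configuration error, not a warning — it would
silently flip signs in the stiffness assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import MuscleGeometryPoly, moment_arm
from .musculotendon import MuscleParams

__all__ = [
    "AGONIST_ROLES",
    "ANTAGONIST_ROLES",
    "ROLES",
    "MuscleEntry",
    "SubjectLegModel",
    "VirtualSubject",
]

ROLES = ("FLEX", "EXT", "PF", "DF")
#: Roles generating positive moment (flexion / dorsiflexion direction).
AGONIST_ROLES = ("FLEX", "DF")
#: Roles generating negative moment (extension / plantarflexion direction).
ANTAGONIST_ROLES = ("EXT", "PF")

DEFAULT_DOFS = ("hip_flexion", "knee_flexion", "ankle_dorsiflexion")


@dataclass(frozen=True)
class MuscleEntry:
    """One muscle of a leg model."""

    name: str
    emg_source: str
    roles: dict[str, str]
    params: MuscleParams
    geometry: MuscleGeometryPoly
    emg_scale: float
    fine_wire: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.emg_scale <= 1:
            raise ValueError(f"{self.name}: emg_scale must lie in (0, 1]")
        for dof, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"{self.name}: unknown role {role!r} for {dof}")


@dataclass(frozen=True)
class SubjectLegModel:
    """All muscles of one leg plus the leg-wide electromechanical delay."""

    name: str
    muscles: tuple[MuscleEntry, ...]
    electromechanical_delay_ms: float
    dofs: tuple[str, ...] = DEFAULT_DOFS

    def __post_init__(self) -> None:
        if self.electromechanical_delay_ms < 0:
            raise ValueError("electromechanical delay must be >= 0")
        names = [m.name for m in self.muscles]
        if len(set(names)) != len(names):
            raise ValueError("muscle names must be unique within a leg")
        neutral = {d: 0.0 for d in self.dofs}
        for m in self.muscles:
            spanned = [d for d in self.dofs if m.geometry.spans(d)]
            if not spanned:
                raise ValueError(f"{m.name}: spans no listed DOF")
            for dof, role in m.roles.items():
                if dof not in self.dofs:
                    raise ValueError(f"{m.name}: role for unknown DOF {dof!r}")
                if not m.geometry.spans(dof):
                    raise ValueError(f"{m.name}: role on unspanned DOF {dof!r}")
                r0 = float(moment_arm(m.geometry, neutral, dof))
                if role in AGONIST_ROLES and r0 <= 0:
                    raise ValueError(
                        f"{m.name}: role {role} on {dof} but moment arm "
                        f"{r0:.4f} m <= 0 at neutral pose"
                    )
                if role in ANTAGONIST_ROLES and r0 >= 0:
                    raise ValueError(
                        f"{m.name}: role {role} on {dof} but moment arm "
                        f"{r0:.4f} m >= 0 at neutral pose"
                    )

    def muscle(self, name: str) -> MuscleEntry:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(f"no muscle {name!r} in leg {self.name!r}")

    def spanning(self, dof: str) -> tuple[MuscleEntry, ...]:
        """Muscles whose geometry depends on ``dof``."""
        return tuple(m for m in self.muscles if m.geometry.spans(dof))


@dataclass(frozen=True)
class VirtualSubject:
    """Two-legged virtual subject with a nominal gait-cycle period (s)."""

    subject_id: str
    legs: dict[str, SubjectLegModel] = field(default_factory=dict)
    cycle_period: float = 1.4

    def __post_init__(self) -> None:
        if len(self.legs) != 2:
            raise ValueError("a subject has exactly two legs")
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be positive")


# ---------------------------------------------------------------------------
# plain-dict (de)serialization, used by the JSON/YAML subject files


def geometry_to_dict(g: MuscleGeometryPoly) -> dict:
    return {
        "dof_labels": list(g.dof_labels),
        "terms": [
            {"exponents": list(e), "coefficient": c} for e, c in g.coefficients.items()
        ],
        "angle_box": {k: list(v) for k, v in g.angle_box.items()},
    }


def geometry_from_dict(d: dict) -> MuscleGeometryPoly:
    return MuscleGeometryPoly(
        dof_labels=tuple(d["dof_labels"]),
        coefficients={
            tuple(t["exponents"]): float(t["coefficient"]) for t in d["terms"]
        },
        angle_box={k: (float(v[0]), float(v[1])) for k, v in d.get("angle_box", {}).items()},
    )


def subject_to_dict(s: VirtualSubject) -> dict:
    return {
        "subject_id": s.subject_id,
        "cycle_period": s.cycle_period,
        "legs": {
            leg.name: {
                "electromechanical_delay_ms": leg.electromechanical_delay_ms,
                "dofs": list(leg.dofs),
                "muscles": [
                    {
                        "name": m.name,
                        "emg_source": m.emg_source,
                        "fine_wire": m.fine_wire,
                        "roles": dict(m.roles),
                        "emg_scale": m.emg_scale,
                        "params": {
                            k: getattr(m.params, k)
                            for k in (
                                "f_max", "l_opt", "l_slack", "alpha_opt",
                                "tau_act", "tau_deact", "shape_A", "fl_width",
                                "passive_strain_ref", "passive_exp_shape",
                            )
                        },
                        "geometry": geometry_to_dict(m.geometry),
                    }
                    for m in leg.muscles
                ],
            }
            for leg in s.legs.values()
        },
    }


def subject_from_dict(d: dict) -> VirtualSubject:
    legs = {}
    for leg_name, ld in d["legs"].items():
        muscles = tuple(
            MuscleEntry(
                name=md["name"],
                emg_source=md["emg_source"],
                fine_wire=bool(md.get("fine_wire", False)),
                roles=dict(md["roles"]),
                emg_scale=float(md["emg_scale"]),
                params=MuscleParams(**md["params"]),
                geometry=geometry_from_dict(md["geometry"]),
            )
            for md in ld["muscles"]
        )
        legs[leg_name] = SubjectLegModel(
            name=leg_name,
            muscles=muscles,
            electromechanical_delay_ms=float(ld["electromechanical_delay_ms"]),
            dofs=tuple(ld["dofs"]),
        )
    return VirtualSubject(
        subject_id=d["subject_id"],
        legs=legs,
        cycle_period=float(d["cycle_period"]),
    )
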