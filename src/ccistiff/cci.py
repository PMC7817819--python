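"""Co-contraction indices over antagonist muscle pairs.

Two pointwise formulations are implemented.  With L(t)/H(t) the lower/higher
of the two envelope values at each time point:

    CCI1(t) = (L/H) · (L + H)        (Rudolph-style; degree-1 homogeneous,
                                      sensitive to overall activity level)
    CCI2(t) = 2·L / (L + H)          (Falconer–Winter-style; scale-invariant
                                      ratio of antagonist activity, in [0, 1])

The L/H assignment is made per time point, not per cycle.  When no activity is
present (H = 0, hence L = 0) both indices are defined as 0: no muscle activity
means no co-contraction, and the per-cycle minimum offset guarantees such
points exist in every cycle.

Pair admissibility mirrors the clinical restriction of the analysis: fine-wire
muscles are excluded (surface EMG only), as are muscles contributing less than
2% of joint stiffness on average; surviving muscles are classified by their
functional role for the DOF (FLEX/DF = agonist group, EXT/PF = antagonist
group) and all agonist × antagonist combinations are enumerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emg_processing import N_GRID, EmgCycleSet
from .subject import AGONIST_ROLES, ANTAGONIST_ROLES, SubjectLegModel

__all__ = [
    "FORMULATIONS",
    "STIFFNESS_FRACTION_MIN",
    "PairCatalog",
    "CciSeries",
    "build_pair_catalog",
    "cci1_point",
    "cci2_point",
    "cci_series",
]

FORMULATIONS = ("CCI1", "CCI2")
#: Minimum mean fractional stiffness contribution for a muscle to be paired.
STIFFNESS_FRACTION_MIN = 0.02


@dataclass(frozen=True)
class PairCatalog:
    """Admissible agonist/antagonist muscles for one DOF, with exclusions."""

    dof: str
    agonists: tuple[str, ...]
    antagonists: tuple[str, ...]
    exclusions: dict[str, str] = field(default_factory=dict)  # muscle -> reason

    def __post_init__(self) -> None:
        if set(self.agonists) & set(self.antagonists):
            raise ValueError("agonist and antagonist sets must be disjoint")
        for m in self.exclusions:
            if m in self.agonists or m in self.antagonists:
                raise ValueError(f"excluded muscle {m!r} appears in a pairing set")

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        """All agonist × antagonist combinations."""
        return tuple((a, b) for a in self.agonists for b in self.antagonists)


@dataclass(frozen=True)
class CciSeries:
    """101-point CCI of one pair / formulation / variant / cycle."""

    pair: tuple[str, str]
    formulation: str
    variant: str
    cycle_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.formulation not in FORMULATIONS:
            raise ValueError(f"unknown formulation {self.formulation!r}")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_GRID,):
            raise ValueError("CCI series must have exactly 101 points")
        if np.any(v < 0):
            raise ValueError("CCI values must be non-negative")
        if self.formulation == "CCI2" and np.any(v > 1 + 1e-12):
            raise ValueError("CCI2 values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


def build_pair_catalog(
    leg: SubjectLegModel,
    dof: str,
    stiffness_fractions: dict[str, float],
) -> PairCatalog:
    """Enumerate admissible antagonist pairs for a DOF.

    ``stiffness_fractions`` comes from
    :func:`ccistiff.joint_stiffness.contribution_fractions` for the same DOF.
    Fine-wire muscles are excluded regardless of contribution; muscles below
    the 2% mean-contribution threshold are excluded; the rest are classified
    by role.  Muscles with no role for this DOF are ignored.
    """
    agonists, antagonists = [], []
    exclusions: dict[str, str] = {}
    for m in leg.spanning(dof):
        role = m.roles.get(dof)
        if role is None:
            continue
        if m.fine_wire:
            exclusions[m.name] = "fine_wire"
            continue
        if stiffness_fractions.get(m.name, 0.0) < STIFFNESS_FRACTION_MIN:
            exclusions[m.name] = "below_2pct"
            continue
        if role in AGONIST_ROLES:
            agonists.append(m.name)
        elif role in ANTAGONIST_ROLES:
            antagonists.append(m.name)
    if not agonists or not antagonists:
        raise ValueError(
            f"no antagonist pairing possible for {dof!r}: "
            f"agonists={agonists}, antagonists={antagonists}, "
            f"excluded={exclusions}"
        )
    return PairCatalog(
        dof=dof,
        agonists=tuple(agonists),
        antagonists=tuple(antagonists),
        exclusions=exclusions,
    )


def _check_nonneg(a, b):
    # envelopes are non-negative by construction; reject negatives defensively
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("CCI inputs must be non-negative envelope values")
    return a, b


def cci1_point(a, b):
    """CCI1 = (L/H)·(L+H), elementwise; 0 where H = 0."""
    a, b = _check_nonneg(a, b)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(hi > 0, lo / np.where(hi > 0, hi, 1.0) * (lo + hi), 0.0)
    return out if out.ndim else float(out)


def cci2_point(a, b):
    """CCI2 = 2L/(L+H), elementwise; 0 where L+H = 0; bounded [0, 1]."""
    a, b = _check_nonneg(a, b)
    lo = np.minimum(a, b)
    s = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(s > 0, 2.0 * lo / np.where(s > 0, s, 1.0), 0.0)
    return out if out.ndim else float(out)


_POINT_FNS = {"CCI1": cci1_point, "CCI2": cci2_point}


def cci_series(
    env_a: EmgCycleSet, env_b: EmgCycleSet, formulation: str
) -> list[CciSeries]:
    """Pointwise CCI over every cycle of a pair of same-variant envelope sets."""
    if formulation not in FORMULATIONS:
        raise ValueError(f"unknown formulation {formulation!r}")
    if env_a.variant != env_b.variant:
        raise ValueError(
            f"variant mismatch: {env_a.variant!r} vs {env_b.variant!r}"
        )
    if env_a.n_cycles != env_b.n_cycles:
        raise ValueError("cycle count mismatch between the two muscles")
    fn = _POINT_FNS[formulation]
    return [
        CciSeries(
            pair=(env_a.muscle, env_b.muscle),
            formulation=formulation,
            variant=env_a.variant,
            cycle_index=i,
            values=np.asarray(fn(env_a.cycles[i], env_b.cycles[i])),
        )
        for i in range(env_a.n_cycles)
    ]
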