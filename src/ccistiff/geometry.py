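"""Polynomial surrogates for musculotendon length over joint angles.

Musculotendon path length is represented as a multivariate polynomial in the
spanned joint angles (the usual surrogate form for musculoskeletal models whose
anatomical geometry has been fitted offline).  Because the surrogate is a
polynomial, the moment arm and its angle gradient are available analytically:

    r_j(θ)      = −∂l_MT/∂θ_j          (moment arm about DOF j, meters)
    ∂r_j/∂θ_j   = −∂²l_MT/∂θ_j²        (meters/radian)

Sign convention (agonist-positive): hip flexion, knee flexion and ankle
dorsiflexion are the positive directions; a muscle whose length decreases as
θ_j increases has r_j > 0 and generates positive (flexion/dorsiflexion) moment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MuscleGeometryPoly",
    "mtu_length",
    "moment_arm",
    "moment_arm_gradient",
]


@dataclass(frozen=True)
class MuscleGeometryPoly:
    """Polynomial musculotendon-length surrogate.

    Parameters
    ----------
    dof_labels
        Ordered labels of the degrees of freedom the polynomial is defined
        over (a muscle *spans* a DOF iff some term with a nonzero coefficient
        depends on it).
    coefficients
        Map from a per-DOF exponent tuple (one integer per entry of
        ``dof_labels``) to a coefficient in meters/radian^k.  The constant
        term (all-zero exponents) must be positive: the muscle has positive
        length at the neutral pose.
    angle_box
        Optional physiologic angle range per DOF, ``(lo, hi)`` radians.
        Evaluation outside the box is allowed but warns.
    """

    dof_labels: tuple[str, ...]
    coefficients: dict[tuple[int, ...], float]
    angle_box: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ndof = len(self.dof_labels)
        for expo in self.coefficients:
            if len(expo) != ndof or any(e < 0 for e in expo):
                raise ValueError(f"bad exponent tuple {expo!r} for {ndof} DOFs")
        const = self.coefficients.get((0,) * ndof, 0.0)
        if const <= 0:
            raise ValueError("constant term must be > 0 (positive neutral length)")

    @property
    def max_degree(self) -> int:
        return max(sum(e) for e in self.coefficients)

    def spans(self, dof: str) -> bool:
        """True iff any nonzero term depends on ``dof``."""
        if dof not in self.dof_labels:
            return False
        j = self.dof_labels.index(dof)
        return any(e[j] > 0 and c != 0.0 for e, c in self.coefficients.items())

    def _angles_vector(self, angles: dict[str, float | np.ndarray]) -> list[np.ndarray]:
        out = []
        for k, lab in enumerate(self.dof_labels):
            try:
                th = np.asarray(angles[lab], dtype=float)
            except KeyError:
                raise KeyError(f"missing angle for DOF {lab!r}") from None
            box = self.angle_box.get(lab)
            if box is not None and (np.any(th < box[0]) or np.any(th > box[1])):
                warnings.warn(
                    f"angle for {lab!r} outside declared box {box}; extrapolating",
                    stacklevel=3,
                )
            out.append(th)
        return out


def _poly_eval(
    geom: MuscleGeometryPoly,
    angles: dict[str, float | np.ndarray],
    d_dof: str | None = None,
    order: int = 0,
) -> np.ndarray:
    """Evaluate the polynomial or its ``order``-th partial w.r.t. ``d_dof``."""
    thetas = geom._angles_vector(angles)
    if d_dof is not None:
        if d_dof not in geom.dof_labels:
            raise KeyError(f"unknown DOF {d_dof!r}; have {geom.dof_labels}")
        j = geom.dof_labels.index(d_dof)
    total = np.zeros(np.broadcast(*thetas).shape if thetas else ())
    for expo, coef in geom.coefficients.items():
        c = float(coef)
        expo = list(expo)
        if d_dof is not None:
            for _ in range(order):
                if expo[j] == 0:
                    c = 0.0
                    break
                c *= expo[j]
                expo[j] -= 1
            if c == 0.0:
                continue
        term = c
        for k, e in enumerate(expo):
            if e:
                term = term * thetas[k] ** e
        total = total + term
    return total


def mtu_length(geom: MuscleGeometryPoly, angles: dict[str, float | np.ndarray]):
    """Musculotendon length l_MT(θ) in meters; must be positive."""
    val = _poly_eval(geom, angles)
    if np.any(val <= 0):
        raise ValueError("non-positive musculotendon length: invalid geometry for pose")
    return val


def moment_arm(geom: MuscleGeometryPoly, angles: dict[str, float | np.ndarray], dof: str):
    """Moment arm r = −∂l_MT/∂θ about ``dof`` (meters, agonist-positive)."""
    return -_poly_eval(geom, angles, d_dof=dof, order=1)


def moment_arm_gradient(
    geom: MuscleGeometryPoly, angles: dict[str, float | np.ndarray], dof: str
):
    """Moment-arm gradient ∂r/∂θ = −∂²l_MT/∂θ² about ``dof`` (m/rad)."""
    return -_poly_eval(geom, angles, d_dof=dof, order=2)
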