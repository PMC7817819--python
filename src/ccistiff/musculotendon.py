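"""Activation dynamics and rigid-tendon Hill-type tendon force.

The tendon is rigid (tendon length fixed at slack length), so fiber kinematics
follow directly from musculotendon length:

    l_f·cosα = l_MT − l_slack            (fiber projection along the tendon)
    l_f·sinα = l_opt·sinα_opt            (constant-thickness pennation)

Tendon force is evaluated isometrically (force–velocity multiplier ≡ 1),
because joint stiffness here is the elastic response of joint moment to joint
*position* only — velocity and activation are held fixed in the partial
derivative:

    F_T = F_max · [a·f_act(l̃) + f_pas(l̃)] · cosα,     l̃ = l_f / l_opt

with a Gaussian active force–length curve f_act(l̃) = exp(−(l̃−1)²/w) and an
exponential passive curve that engages above optimal length.  The analytic
length slope ∂F_T/∂l_MT (chain rule through l_f, α, l̃ at fixed activation) is
the muscle-level ingredient of joint stiffness.

Excitation→activation is a first-order ODE with an activation-dependent time
constant (fast rise, slow fall), integrated semi-implicitly, followed by an
optional exponential shape nonlinearity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MuscleParams",
    "ActivationSeries",
    "excitation_to_activation",
    "tendon_force",
    "tendon_force_slope",
]


@dataclass(frozen=True)
class MuscleParams:
    """Hill-type parameters of one musculotendon unit.

    Attributes
    ----------
    f_max : maximal isometric force, N
    l_opt : optimal fiber length, m
    l_slack : tendon slack length, m (constant — rigid tendon)
    alpha_opt : pennation angle at optimal fiber length, rad
    tau_act, tau_deact : activation / deactivation time constants, s
    shape_A : activation nonlinearity shape in [−3, 0), or ``None`` to skip
    fl_width : Gaussian active force–length width (dimensionless)
    passive_strain_ref : fiber strain at which passive force reaches f_max
    passive_exp_shape : exponential shape of the passive curve
    """

    f_max: float
    l_opt: float
    l_slack: float
    alpha_opt: float = 0.0
    tau_act: float = 0.015
    tau_deact: float = 0.050
    shape_A: float | None = -1.5
    fl_width: float = 0.45
    passive_strain_ref: float = 0.6
    passive_exp_shape: float = 4.0

    def __post_init__(self) -> None:
        if self.f_max <= 0 or self.l_opt <= 0:
            raise ValueError("f_max and l_opt must be positive")
        if self.l_slack < 0:
            raise ValueError("l_slack must be non-negative")
        if not 0 <= self.alpha_opt < math.pi / 2:
            raise ValueError("alpha_opt must lie in [0, pi/2)")
        if self.tau_act > self.tau_deact:
            raise ValueError("physiologic activation requires tau_act <= tau_deact")
        if self.fl_width <= 0:
            raise ValueError("fl_width must be positive")
        if self.shape_A is not None and not -3 <= self.shape_A < 0:
            raise ValueError("shape_A must lie in [-3, 0) or be None")


@dataclass(frozen=True)
class ActivationSeries:
    """Muscle activation samples in [0, 1] at a fixed rate."""

    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("activation must stay within [0, 1]")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))


def excitation_to_activation(
    excitation: np.ndarray,
    params: MuscleParams,
    rate: float,
    a0: float = 0.0,
) -> ActivationSeries:
    """Integrate first-order activation dynamics over an excitation series.

    da/dt = (u − a)/τ(a, u) with τ = tau_act·(0.5 + 1.5a) when u > a and
    τ = tau_deact/(0.5 + 1.5a) otherwise; semi-implicit (backward-Euler in the
    linear part) update, unconditionally stable and bounded in [0, 1].  The
    optional nonlinearity a' = (e^{A·a} − 1)/(e^{A} − 1) is applied afterwards.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    u = np.asarray(excitation, dtype=float)
    if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
        raise ValueError("excitation must lie in [0, 1]")
    u = np.clip(u, 0.0, 1.0)
    dt = 1.0 / rate
    a = np.empty_like(u)
    prev = float(np.clip(a0, 0.0, 1.0))
    if u.ndim == 1:
        ta, td = params.tau_act, params.tau_deact
        ul = u.tolist()
        al = a  # fill in place
        for k, uk in enumerate(ul):
            if uk > prev:
                tau = ta * (0.5 + 1.5 * prev)
            else:
                tau = td / (0.5 + 1.5 * prev)
            prev = (prev + dt * uk / tau) / (1.0 + dt / tau)
            al[k] = prev
    else:
        for k in range(u.shape[-1]):
            uk = u[..., k]
            tau = np.where(
                uk > prev,
                params.tau_act * (0.5 + 1.5 * prev),
                params.tau_deact / (0.5 + 1.5 * prev),
            )
            prev = (prev + dt * uk / tau) / (1.0 + dt / tau)
            a[..., k] = prev
    if params.shape_A is not None:
        A = params.shape_A
        a = (np.exp(A * a) - 1.0) / (math.exp(A) - 1.0)
    return ActivationSeries(values=np.clip(a, 0.0, 1.0), rate=rate)


def _fiber_state(params: MuscleParams, l_mt):
    """Return (l_f, cosα, l̃) under the rigid-tendon constraint."""
    l_mt = np.asarray(l_mt, dtype=float)
    x = l_mt - params.l_slack  # fiber projection along tendon
    h = params.l_opt * math.sin(params.alpha_opt)  # constant muscle thickness
    if h == 0.0:
        if np.any(x <= 0):
            raise ValueError(
                "l_mt <= l_slack with zero pennation: non-positive fiber length"
            )
        l_f = x
        cos_a = np.ones_like(x)
    else:
        l_f = np.hypot(x, h)
        cos_a = x / l_f
    return l_f, cos_a, l_f / params.l_opt


def _active_fl(params: MuscleParams, l_tilde):
    return np.exp(-((l_tilde - 1.0) ** 2) / params.fl_width)


def _passive_fl(params: MuscleParams, l_tilde):
    s = params.passive_exp_shape
    e = np.maximum(np.asarray(l_tilde, dtype=float) - 1.0, 0.0)
    return (np.exp(s * e / params.passive_strain_ref) - 1.0) / (math.exp(s) - 1.0)


def tendon_force(params: MuscleParams, a, l_mt):
    """Isometric rigid-tendon force F_T(a, l_MT) in newtons (≥ 0)."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("activation must lie in [0, 1]")
    _, cos_a, lt = _fiber_state(params, l_mt)
    return params.f_max * (a * _active_fl(params, lt) + _passive_fl(params, lt)) * cos_a


def tendon_force_slope(params: MuscleParams, a, l_mt):
    """Analytic ∂F_T/∂l_MT (N/m) at fixed activation.

    With x = l_MT − l_slack, h = l_opt·sinα_opt, l_f = √(x²+h²):
    dl_f/dl_MT = cosα and d(cosα)/dl_MT = h²/l_f³, so

        ∂F_T/∂l_MT = F_max·[ g'(l̃)·cosα²/l_opt + g(l̃)·h²/l_f³ ],

    where g(l̃) = a·f_act + f_pas.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("activation must lie in [0, 1]")
    l_f, cos_a, lt = _fiber_state(params, l_mt)
    h = params.l_opt * math.sin(params.alpha_opt)
    g = a * _active_fl(params, lt) + _passive_fl(params, lt)
    d_act = -2.0 * (lt - 1.0) / params.fl_width * _active_fl(params, lt)
    s = params.passive_exp_shape
    d_pas = np.where(
        lt > 1.0,
        (s / params.passive_strain_ref)
        * np.exp(s * np.maximum(lt - 1.0, 0.0) / params.passive_strain_ref)
        / (math.exp(s) - 1.0),
        0.0,
    )
    dg = a * d_act + d_pas
    return params.f_max * (dg * cos_a**2 / params.l_opt + g * h**2 / l_f**3)
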