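"""Virtual hemiparetic subject and gait-trial generator with known ground truth.

The generator emulates the kind of dataset the analysis needs without any
recorded data: 16 muscles per leg sampled at 1,000 Hz, ~10 gait cycles,
burst-like activation envelopes, leg-specific electromechanical delays
(82 / 93 ms by default), muscle-specific EMG scale factors in (0, 1], and a
controllable degree of coupling between antagonist co-activation and joint
stiffness.

World model
-----------
* Kinematics: each sagittal DOF is a sum of two sinusoidal harmonics of the
  gait cycle with physiologic amplitudes (motion capture is out of scope).
* Envelopes: per muscle and per cycle, a sum of Gaussian bursts (center and
  width in % of cycle) with multiplicative lognormal cycle-to-cycle amplitude
  jitter (σ = 0.15 by default).
* Coupling: under the ``coupled`` scenario a joint-wide co-contraction drive
  sets the burst timing shared by all muscles and correlates the amplitude
  jitter across muscles (strength 1 = fully shared).  The ``independent``
  scenario is the negative-control world: every muscle's burst *timing and*
  amplitude are drawn independently per cycle, so no systematic within-cycle
  alignment between any antagonist pair's co-activation and joint stiffness
  survives.
* Raw EMG: band-limited (40–450 Hz) Gaussian carrier amplitude-modulated by
  (envelope + noise floor); zero mean by construction.
* Ground truth: tendon forces use envelopes shifted by the configured
  electromechanical delay and scaled by the muscle's EMG scale factor, passed
  through activation dynamics — the delay is genuinely present in the
  synthetic mechanics and recoverable downstream.  True stiffness is computed
  by the :mod:`ccistiff.joint_stiffness` assembly from those activations.

Everything is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .emg_processing import delay_shift, segment_cycles
from .geometry import MuscleGeometryPoly
from .joint_stiffness import stiffness_series
from .musculotendon import MuscleParams, excitation_to_activation
from .subject import (
    DEFAULT_DOFS,
    MuscleEntry,
    SubjectLegModel,
    VirtualSubject,
)

__all__ = [
    "MuscleSpec",
    "GeneratorConfig",
    "CouplingScenario",
    "GaitTrial",
    "GroundTruth",
    "make_subject",
    "make_gait_trial",
    "synthesize_raw_emg",
    "DEFAULT_MUSCLE_SPECS",
]

LEG_NAMES = ("non-paretic", "paretic")

ANGLE_BOX = {
    "hip_flexion": (-0.7, 0.7),
    "knee_flexion": (-0.9, 0.9),
    "ankle_dorsiflexion": (-0.45, 0.45),
}

#: Kinematic harmonics per DOF: (mean, A1, phi1, A2, phi2) in radians.
KINEMATIC_HARMONICS = {
    "hip_flexion": (0.05, 0.28, 1.9, 0.05, 0.6),
    "knee_flexion": (0.22, 0.20, 4.4, 0.12, 1.2),
    "ankle_dorsiflexion": (0.0, 0.10, 3.6, 0.05, 0.9),
}


@dataclass(frozen=True)
class MuscleSpec:
    """Generator-side description of one muscle.

    ``moment_arms`` maps DOF → moment arm at the neutral pose (m, agonist
    positive); ``roles`` maps DOF → FLEX/EXT/PF/DF; ``scales`` holds the EMG
    scale factor per leg (non-paretic, paretic); ``bursts`` is the muscle's
    gait-phase activity pattern as (center %, width %, relative amplitude).
    """

    name: str
    emg_source: str
    roles: dict[str, str]
    moment_arms: dict[str, float]
    f_max: float
    l_opt: float
    scales: tuple[float, float]
    bursts: tuple[tuple[float, float, float], ...]
    alpha_opt: float = 0.1
    fine_wire: bool = False
    curvature: float = 0.006  # quadratic length coefficient per DOF (m/rad^2)


def _spec(name, src, roles, arms, f_max, l_opt, scales, bursts, **kw) -> MuscleSpec:
    return MuscleSpec(
        name=name, emg_source=src, roles=roles, moment_arms=arms,
        f_max=f_max, l_opt=l_opt, scales=scales, bursts=tuple(bursts), **kw
    )


# 16 muscles per leg mirroring a clinical lower-limb EMG montage; scale factors
# follow the calibrated subject-1 values (left = non-paretic, right = paretic).
DEFAULT_MUSCLE_SPECS: tuple[MuscleSpec, ...] = (
    _spec("addlong", "Adductor longus", {"hip_flexion": "FLEX"},
          {"hip_flexion": 0.035}, 620, 0.12, (0.33, 0.07),
          [(8, 7, 1.0), (88, 8, 0.5)]),
    _spec("glmax2", "Gluteus maximus", {"hip_flexion": "EXT"},
          {"hip_flexion": -0.060}, 1500, 0.15, (0.33, 0.20),
          [(5, 8, 1.0), (93, 6, 0.4)]),
    _spec("iliacus", "Iliopsoas", {"hip_flexion": "FLEX"},
          {"hip_flexion": 0.035}, 850, 0.11, (0.05, 0.05),
          [(55, 9, 1.0)], fine_wire=True),
    _spec("psoas", "Iliopsoas", {"hip_flexion": "FLEX"},
          {"hip_flexion": 0.038}, 1000, 0.12, (0.99, 0.82),
          [(55, 9, 1.0)], fine_wire=True),
    _spec("semimem", "Semimem", {"hip_flexion": "EXT", "knee_flexion": "FLEX"},
          {"hip_flexion": -0.055, "knee_flexion": 0.035}, 1300, 0.10,
          (0.35, 0.40), [(3, 7, 1.0), (92, 7, 0.8)]),
    _spec("semiten", "Semimem", {"hip_flexion": "EXT", "knee_flexion": "FLEX"},
          {"hip_flexion": -0.055, "knee_flexion": 0.040}, 410, 0.13,
          (0.30, 0.40), [(3, 7, 1.0), (92, 7, 0.8)]),
    _spec("bflh", "Bflh", {"hip_flexion": "EXT", "knee_flexion": "FLEX"},
          {"hip_flexion": -0.055, "knee_flexion": 0.030}, 900, 0.11,
          (0.76, 0.38), [(4, 7, 1.0), (90, 8, 0.7)]),
    _spec("bfsh", "Bflh", {"knee_flexion": "FLEX"},
          {"knee_flexion": 0.030}, 420, 0.11, (0.76, 0.39),
          [(65, 10, 1.0), (92, 6, 0.5)]),
    _spec("recfem", "Rectus femoris", {"hip_flexion": "FLEX", "knee_flexion": "EXT"},
          {"hip_flexion": 0.040, "knee_flexion": -0.045}, 1200, 0.10,
          (0.48, 0.27), [(10, 8, 1.0), (58, 8, 0.6)]),
    _spec("vasmed", "Vastus medialis", {"knee_flexion": "EXT"},
          {"knee_flexion": -0.045}, 1400, 0.10, (0.27, 0.50),
          [(12, 9, 1.0)]),
    _spec("vaslat", "Vastus lateralis", {"knee_flexion": "EXT"},
          {"knee_flexion": -0.045}, 1900, 0.10, (0.32, 0.11),
          [(12, 9, 1.0)]),
    _spec("gasmed", "Gasmed", {"knee_flexion": "FLEX", "ankle_dorsiflexion": "PF"},
          {"knee_flexion": 0.020, "ankle_dorsiflexion": -0.048}, 1300, 0.09,
          (0.14, 0.14), [(38, 10, 1.0)], alpha_opt=0.3),
    _spec("gaslat", "Gasmed", {"knee_flexion": "FLEX", "ankle_dorsiflexion": "PF"},
          {"knee_flexion": 0.020, "ankle_dorsiflexion": -0.048}, 620, 0.09,
          (0.05, 0.12), [(38, 10, 1.0)], alpha_opt=0.2),
    _spec("tibant", "Tibialis anterior", {"ankle_dorsiflexion": "DF"},
          {"ankle_dorsiflexion": 0.040}, 900, 0.09, (0.61, 1.00),
          [(3, 6, 1.0), (65, 18, 0.7)]),
    _spec("soleus", "Soleus", {"ankle_dorsiflexion": "PF"},
          {"ankle_dorsiflexion": -0.050}, 3500, 0.08, (0.65, 0.96),
          [(40, 11, 1.0)], alpha_opt=0.4),
    _spec("tibpost", "Tibialis posterior", {"ankle_dorsiflexion": "PF"},
          {"ankle_dorsiflexion": -0.040}, 1500, 0.07, (0.05, 0.05),
          [(35, 12, 1.0)], fine_wire=True),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated-world settings of the virtual subject and trial generator."""

    muscle_specs: tuple[MuscleSpec, ...] = DEFAULT_MUSCLE_SPECS
    delays_ms: tuple[float, float] = (82.0, 93.0)  # (non-paretic, paretic)
    cycle_period: float = 1.4  # s; low-pass cutoff is then 3.5/1.4 = 2.5 Hz
    emg_rate: float = 1000.0
    scale_mode: str = "table"  # "table" (calibrated values) or "uniform" draw
    jitter_sigma: float = 0.15  # lognormal cycle-to-cycle amplitude jitter
    base_amplitude: float = 0.7  # peak envelope level before jitter
    burst_amp_scale: float = 1.0  # global gain on burst amplitudes
    noise_floor: float = 0.05  # carrier floor relative to full-scale envelope
    null_bursts_per_cycle: int = 3  # unstructured activity density of the null world
    l_tilde_neutral: float = 0.95  # normalized fiber length at the neutral pose
    lead_in_s: float = 0.5  # pre-trial record before the first heel strike
    tail_s: float = 0.3


@dataclass(frozen=True)
class CouplingScenario:
    """Antagonist coupling scenario: 'coupled' (with strength) or 'independent'."""

    kind: str
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("coupled", "independent"):
            raise ValueError("coupling kind must be 'coupled' or 'independent'")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must lie in [0, 1]")

    @classmethod
    def parse(cls, value) -> "CouplingScenario":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            try:
                return cls(kind="coupled", strength=float(value))
            except ValueError:
                return cls(kind=value, strength=0.0 if value == "independent" else 1.0)
        return cls(kind="coupled", strength=float(value))


@dataclass(frozen=True)
class GaitTrial:
    """Continuous kinematics + raw EMG + cycle events for both legs.

    Channel keys are composite ``"leg/muscle"`` and ``"leg/dof"`` labels.
    """

    emg_rate: float
    kin_rate: float
    emg_channels: dict[str, np.ndarray]
    joint_angles: dict[str, np.ndarray]
    joint_velocities: dict[str, np.ndarray]
    heel_strikes: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        hs = np.asarray(self.heel_strikes, dtype=float)
        if hs.size < 2:
            raise ValueError("a trial needs at least two heel strikes")
        object.__setattr__(self, "heel_strikes", hs)

    @property
    def n_cycles(self) -> int:
        return self.heel_strikes.size - 1

    @property
    def time(self) -> np.ndarray:
        n = len(next(iter(self.emg_channels.values())))
        return self.t0 + np.arange(n) / self.emg_rate


@dataclass(frozen=True)
class GroundTruth:
    """True envelopes/activations (continuous) and per-cycle true stiffness."""

    true_envelopes: dict[str, np.ndarray]  # "leg/muscle" -> samples in [0, 1]
    true_activations: dict[str, np.ndarray]
    true_stiffness: dict[str, np.ndarray]  # "leg/dof" -> (n_cycles, 101)
    burst_amplitudes: dict[str, np.ndarray] = field(default_factory=dict)
    # "leg/muscle" -> per-cycle peak burst amplitude (for coupling diagnostics)


# ---------------------------------------------------------------------------
# subject


def _geometry_for(spec: MuscleSpec) -> MuscleGeometryPoly:
    dofs = tuple(DEFAULT_DOFS)
    coeffs: dict[tuple[int, ...], float] = {}
    c0 = 0.15 + 2.0 * spec.l_opt
    coeffs[(0,) * len(dofs)] = c0
    spanned = [d for d in dofs if d in spec.moment_arms]
    for d in spanned:
        j = dofs.index(d)
        lin = [0] * len(dofs)
        lin[j] = 1
        coeffs[tuple(lin)] = -spec.moment_arms[d]  # r = -dl/dθ
        quad = [0] * len(dofs)
        quad[j] = 2
        coeffs[tuple(quad)] = spec.curvature  # ∂r/∂θ = -2c2 < 0 (stabilizing)
    if len(spanned) == 2:  # mild biarticular coupling term
        cross = [0] * len(dofs)
        for d in spanned:
            cross[dofs.index(d)] = 1
        coeffs[tuple(cross)] = 0.002
    return MuscleGeometryPoly(
        dof_labels=dofs, coefficients=coeffs, angle_box=dict(ANGLE_BOX)
    )


def _params_for(spec: MuscleSpec, l_tilde_neutral: float) -> MuscleParams:
    geom_c0 = 0.15 + 2.0 * spec.l_opt
    l_f0 = l_tilde_neutral * spec.l_opt
    h = spec.l_opt * math.sin(spec.alpha_opt)
    if l_f0 <= h:
        raise ValueError(f"{spec.name}: neutral fiber shorter than muscle thickness")
    x0 = math.sqrt(l_f0**2 - h**2)
    return MuscleParams(
        f_max=spec.f_max,
        l_opt=spec.l_opt,
        l_slack=geom_c0 - x0,
        alpha_opt=spec.alpha_opt,
    )


def make_subject(
    config: GeneratorConfig | None = None, seed: int = 0
) -> VirtualSubject:
    """Build the two-legged virtual subject from generator settings.

    Deterministic for a fixed (config, seed).  A DOF without at least one
    agonist (FLEX/DF) and one antagonist (EXT/PF) muscle is rejected — no
    antagonism means nothing downstream can be computed.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5A]))
    spanned_roles: dict[str, set[str]] = {}
    for spec in config.muscle_specs:
        for dof, role in spec.roles.items():
            spanned_roles.setdefault(dof, set()).add(role)
    for dof, roles in spanned_roles.items():
        if not roles & {"FLEX", "DF"} or not roles & {"EXT", "PF"}:
            raise ValueError(
                f"config invalid: DOF {dof!r} has no antagonism (roles {sorted(roles)})"
            )
    legs = {}
    for leg_idx, leg_name in enumerate(LEG_NAMES):
        muscles = []
        for spec in config.muscle_specs:
            if config.scale_mode == "table":
                scale = spec.scales[leg_idx]
            elif config.scale_mode == "uniform":
                scale = float(rng.uniform(0.05, 1.0))
            else:
                raise ValueError(f"unknown scale_mode {config.scale_mode!r}")
            muscles.append(
                MuscleEntry(
                    name=spec.name,
                    emg_source=spec.emg_source,
                    fine_wire=spec.fine_wire,
                    roles=dict(spec.roles),
                    params=_params_for(spec, config.l_tilde_neutral),
                    geometry=_geometry_for(spec),
                    emg_scale=scale,
                )
            )
        legs[leg_name] = SubjectLegModel(
            name=leg_name,
            muscles=tuple(muscles),
            electromechanical_delay_ms=config.delays_ms[leg_idx],
        )
    return VirtualSubject(
        subject_id=f"virtual-{seed}", legs=legs, cycle_period=config.cycle_period
    )


# ---------------------------------------------------------------------------
# trial


#: Shared co-contraction drive bursts for the coupled scenario (center %,
#: width %, relative amplitude): loading response, push-off, mid-swing.
SHARED_DRIVE_BURSTS = ((10.0, 8.0, 1.0), (45.0, 10.0, 0.8), (78.0, 9.0, 0.45))


def _burst_profile(
    t: np.ndarray,
    lead_in: float,
    period: float,
    n_cycles: int,
    bursts_per_cycle,  # callable cycle -> iterable of (center%, width%, amp)
) -> np.ndarray:
    """Sum per-cycle Gaussian bursts over absolute time (edges use neighbors)."""
    env = np.zeros_like(t)
    for k in range(-1, n_cycles + 1):
        src = min(max(k, 0), n_cycles - 1)
        for center, width, amp in bursts_per_cycle(src):
            mu = lead_in + (k + center / 100.0) * period
            sig = max(width, 1e-6) / 100.0 * period
            env += amp * np.exp(-((t - mu) ** 2) / (2.0 * sig**2))
    return np.clip(env, 0.0, 1.0)


def synthesize_raw_emg(
    envelope: np.ndarray, rate: float, noise_floor: float, seed
) -> np.ndarray:
    """Amplitude-modulated band-limited carrier for a true envelope.

    The carrier is Gaussian white noise band-passed to 40–450 Hz (the standard
    surface-EMG band) and normalized to unit RMS; the returned record is
    carrier × (envelope + noise_floor) and has (near-)zero mean.
    """
    if not 0 <= noise_floor < 0.2:
        raise ValueError("noise_floor must lie in [0, 0.2)")
    if rate <= 2 * 450.0:
        raise ValueError("rate must exceed 900 Hz (twice the 450 Hz carrier band)")
    if rate < 1000.0:
        warnings.warn("sampling below the study's 1,000 Hz rate", stacklevel=2)
    env = np.asarray(envelope, dtype=float)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(env.shape[-1])
    sos = signal.butter(4, [40.0 / (rate / 2), 450.0 / (rate / 2)], "bandpass",
                        output="sos")
    carrier = signal.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(carrier**2))
    if rms > 0:
        carrier = carrier / rms
    return carrier * (env + noise_floor)


def make_gait_trial(
    subject: VirtualSubject,
    n_cycles: int = 10,
    coupling: CouplingScenario | str | float = "coupled",
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> tuple[GaitTrial, GroundTruth]:
    """Generate a multi-cycle gait trial and its ground truth for ``subject``.

    ``coupling`` may be a :class:`CouplingScenario`, the strings ``"coupled"``
    / ``"independent"``, or a numeric coupled-strength in [0, 1].
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    scenario = CouplingScenario.parse(coupling)
    config = config or GeneratorConfig()
    rate = config.emg_rate
    T = subject.cycle_period
    lead, tail = config.lead_in_s, config.tail_s
    duration = lead + n_cycles * T + tail
    t = np.arange(int(round(duration * rate))) / rate
    heel_strikes = lead + T * np.arange(n_cycles + 1)

    # kinematics (identical for both legs of this symmetric virtual subject)
    phase = 2 * np.pi * (t - lead) / T
    angles_one = {}
    vels_one = {}
    for dof, (mean, a1, p1, a2, p2) in KINEMATIC_HARMONICS.items():
        angles_one[dof] = mean + a1 * np.sin(phase + p1) + a2 * np.sin(2 * phase + p2)
        vels_one[dof] = (2 * np.pi / T) * (
            a1 * np.cos(phase + p1) + 2 * a2 * np.cos(2 * phase + p2)
        )

    ss = np.random.SeedSequence([seed, 0xC0])
    specs = {s.name: s for s in config.muscle_specs}
    emg_channels: dict[str, np.ndarray] = {}
    true_env: dict[str, np.ndarray] = {}
    true_act: dict[str, np.ndarray] = {}
    true_stiff: dict[str, np.ndarray] = {}
    burst_amps: dict[str, np.ndarray] = {}
    joint_angles: dict[str, np.ndarray] = {}
    joint_vels: dict[str, np.ndarray] = {}

    for leg_name, leg in subject.legs.items():
        leg_ss = np.random.SeedSequence(
            [seed, 0xC1, LEG_NAMES.index(leg_name)]
        )
        rng_common = np.random.default_rng(leg_ss.spawn(1)[0])
        # one shared lognormal gain and timing per cycle for the coupled drive
        z_common = rng_common.standard_normal(n_cycles)
        for dof in leg.dofs:
            joint_angles[f"{leg_name}/{dof}"] = angles_one[dof].copy()
            joint_vels[f"{leg_name}/{dof}"] = vels_one[dof].copy()

        for m_idx, muscle in enumerate(leg.muscles):
            spec = specs[muscle.name]
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [seed, 0xC2, LEG_NAMES.index(leg_name), m_idx]
                )
            )
            z_own = rng.standard_normal(n_cycles)
            c = scenario.strength if scenario.kind == "coupled" else 0.0
            z = c * z_common + math.sqrt(1.0 - c**2) * z_own
            gains = np.exp(config.jitter_sigma * z - config.jitter_sigma**2 / 2)
            amp = config.base_amplitude * config.burst_amp_scale
            per_cycle_amp = np.clip(amp * gains, 0.0, 1.0)

            if scenario.kind == "independent":
                # null world: unstructured activity — random burst timing and
                # independent amplitudes per cycle per muscle
                n_b = max(config.null_bursts_per_cycle, 1)
                centers = rng.uniform(8.0, 92.0, size=(n_cycles, n_b))
                widths = rng.uniform(6.0, 12.0, size=(n_cycles, n_b))
                rel = rng.uniform(0.4, 1.0, size=(n_cycles, n_b))

                def bursts_for(k, centers=centers, widths=widths, rel=rel,
                               per_cycle_amp=per_cycle_amp):
                    return [
                        (centers[k, i], widths[k, i], per_cycle_amp[k] * rel[k, i])
                        for i in range(centers.shape[1])
                    ]
            else:
                own = spec.bursts
                shared = SHARED_DRIVE_BURSTS
                cs = scenario.strength

                def bursts_for(k, own=own, shared=shared, cs=cs,
                               per_cycle_amp=per_cycle_amp):
                    out = [
                        (b[0], b[1], per_cycle_amp[k] * b[2] * cs) for b in shared
                    ]
                    out += [
                        (b[0], b[1], per_cycle_amp[k] * b[2] * (1.0 - cs))
                        for b in own
                    ]
                    return out

            env = _burst_profile(t, lead, T, n_cycles, bursts_for)
            key = f"{leg_name}/{muscle.name}"
            true_env[key] = env
            burst_amps[key] = per_cycle_amp
            emg_channels[key] = synthesize_raw_emg(
                env, rate, config.noise_floor, rng.integers(2**31)
            )
            exc = np.clip(
                delay_shift(env, rate, leg.electromechanical_delay_ms)
                * muscle.emg_scale,
                0.0,
                1.0,
            )
            true_act[key] = excitation_to_activation(exc, muscle.params, rate).values

        # ground-truth stiffness from true activations via the analytic assembly
        act_cycles = {
            m.name: segment_cycles(
                true_act[f"{leg_name}/{m.name}"], rate, heel_strikes
            )
            for m in leg.muscles
        }
        ang_cycles = {
            dof: segment_cycles(angles_one[dof], rate, heel_strikes)
            for dof in leg.dofs
        }
        for dof in leg.dofs:
            ks = np.empty((n_cycles, 101))
            for k in range(n_cycles):
                ks[k] = stiffness_series(
                    leg,
                    {name: cyc[k] for name, cyc in act_cycles.items()},
                    {d: cyc[k] for d, cyc in ang_cycles.items()},
                    dof,
                    cycle_index=k,
                ).k_joint
            true_stiff[f"{leg_name}/{dof}"] = ks

    trial = GaitTrial(
        emg_rate=rate,
        kin_rate=rate,
        emg_channels=emg_channels,
        joint_angles=joint_angles,
        joint_velocities=joint_vels,
        heel_strikes=heel_strikes,
    )
    truth = GroundTruth(
        true_envelopes=true_env,
        true_activations=true_act,
        true_stiffness=true_stiff,
        burst_amplitudes=burst_amps,
    )
    return trial, truth
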