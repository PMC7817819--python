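# Methods

This note documents the models, numerical choices, and limits of validity of
the `ccistiff` pipeline, in the order data flows through it.

## EMG envelope processing

Raw EMG is high-pass filtered at 40 Hz, demeaned, full-wave rectified, and
low-pass filtered at 3.5/period Hz (2.5 Hz for the default 1.4 s cycle), each
filter a 4th-order Butterworth applied forward–backward (zero phase, effective
8th-order magnitude response; the design order is a parameter for users who
read "4th order zero phase-lag" as the effective order). Filters run on the
continuous record with reflective padding of 3× the corner-period settling
length (≈1.2 s for the 2.5 Hz low-pass at 1 kHz), so edge transients never
reach analyzed cycles; records shorter than the padding are rejected. Small
negative low-pass ripple is clamped to zero before normalization — envelopes
are physically non-negative, and the per-cycle offset would otherwise shift
whole cycles by the ripple magnitude.

Cycles are segmented heel strike to heel strike and linearly resampled to 101
points (0–100% in 1% steps; linear interpolation is monotone and
artifact-free). Each cycle is offset by its minimum and the set divided by its
maximum over all analyzed cycles, in that order: this makes both normalization
contracts exact on the analyzed grid (per-cycle min ≡ 0, basic-variant global
max ≡ 1); the reverse order can only satisfy them approximately. The trial
maximum is taken within the single analyzed trial.

The electromechanical delay (82 ms non-paretic / 93 ms paretic leg by
default) shifts the *continuous* envelope before segmentation; the leading gap
holds the first value, and the generator provides ≥0.5 s of lead-in so no
analyzed cycle touches it. Variant algebra: scaled = basic × scale,
calibrated = delayed × scale, pointwise.

## Musculotendon model

Rigid tendon: tendon length is frozen at slack length, so fiber kinematics
follow from musculotendon length alone, with constant-thickness pennation
(l_f·sinα = l_opt·sinα_opt). Tendon force is
F = F_max·[a·exp(−(l̃−1)²/w) + f_pas(l̃)]·cosα with w = 0.45 and an
exponential passive curve engaging above optimal length (reference strain 0.6,
shape 4). Force–velocity is fixed at 1: stiffness here is the elastic response
of joint moment to *position* at fixed activation and velocity, which is what
distinguishes it from quasi-stiffness. The length slope ∂F/∂l_MT is closed
form (chain rule through fiber length, pennation and normalized length); the
passive curve is continuous but has a C¹ kink at l̃ = 1, where the half-open
definition (passive ≡ 0 for l̃ ≤ 1) applies.

Excitation→activation is the first-order ODE da/dt = (u−a)/τ(a,u) with
τ = τ_act·(0.5+1.5a) on the way up and τ_deact/(0.5+1.5a) on the way down
(τ_act = 15 ms, τ_deact = 50 ms), integrated semi-implicitly at the sampling
rate — unconditionally stable and bounded in [0,1] — followed by the shape
nonlinearity a′ = (e^{Aa}−1)/(e^{A}−1), A = −1.5. A first-order scheme at
1 kHz carries O(dt/τ) ≈ 0.3–1% step-size error against the converged
solution; the tests assert that bound and first-order convergence rather than
a tighter figure the scheme cannot deliver. Excitation is the calibrated
envelope (delayed × muscle scale factor), resampled to the integration grid;
in the pipeline's stiffness stage the dynamics run over the concatenated
101-point cycles (state carried across cycle boundaries).

## Joint stiffness

K_joint = −∂M/∂θ expands, using r = −∂l_MT/∂θ, to
K = Σ_i [r²·∂F/∂l − (∂r/∂θ)·F]. The printed sign of this expansion differs
between sources depending on the moment-arm convention; here the expansion is
*defined* by the derivative and continuously gated against a central-difference
oracle on −∂M/∂θ (1e-4 relative at all 101 points on random models). Sign
conventions are explicit: hip flexion, knee flexion, ankle dorsiflexion
positive; r > 0 means flexion/dorsiflexion moment; every muscle's declared
functional role (FLEX/EXT, DF/PF) is validated against the sign of its moment
arm at the neutral pose at model construction — a mismatch is a configuration
error. A muscle spans a DOF iff its length polynomial depends on that angle;
biarticular muscles contribute to each spanned DOF independently (single-DOF
partials carry no cross-joint terms).

Per-muscle mean contribution fractions (mean over cycle points of
|K_mus|/Σ|K_mus|) drive the pairing exclusion: muscles below 2% are dropped
from CCI pairing, as are all fine-wire-instrumented muscles (iliacus, psoas,
tibialis posterior) — surface EMG is what a clinic has.

## CCI computation and statistics

CCI1 = (L/H)(L+H) and CCI2 = 2L/(L+H), with the lower/higher assignment made
per time point. Both are defined as 0 when no activity is present (H = 0
resp. L+H = 0): no activity means no co-contraction, and the per-cycle offset
guarantees such points exist. CCI1 is degree-1 homogeneous and CCI2
scale-invariant — the algebraic root of why scale factors affect CCI1-based
but not CCI2-based correlations. Pairs are enumerated exhaustively over
surviving agonist × antagonist combinations; reports keep the best pair per
(joint, formulation, variant), ties broken by lexicographically first pair
name (logged).

Per-cycle Pearson r uses the standard product-moment form; zero-variance
cycles are reported missing (NaN, logged), not zero. Summaries use the sample
(n−1) SD. Strength classes are half-open on |r̄|: negligible < 0.3 ≤ weak
< 0.5 ≤ moderate < 0.7 ≤ strong (the sign is carried separately, so strongly
negative associations classify by magnitude). Formulations are compared by a
two-sided Wilcoxon rank-sum on the per-cycle r sets, exact for combined
n ≤ 20 without ties, normal approximation with tie correction otherwise; no
multiple-testing correction is applied.

## Synthetic world

The generator emulates: 16 muscles per leg mirroring a clinical lower-limb
montage (Table-style roles, surface sources with shared channels for synergist
groups, three fine-wire channels), EMG scale factors from the calibrated
subject-1 table (a uniform (0.05, 1] draw is available), 1,000 Hz sampling,
a 1.4 s cycle, leg delays 82/93 ms. Kinematics are two sinusoidal harmonics
per DOF with physiologic amplitudes (hip ≈ ±0.3 rad, knee mean 0.22 ± 0.3,
ankle ± 0.15); both legs share events and kinematics — asymmetry lives in
delays, scale factors, and stochastic draws. Raw EMG is unit-RMS Gaussian
noise band-passed to 40–450 Hz, amplitude-modulated by (envelope + 0.05
noise floor). Geometry is quadratic per spanned DOF with positive curvature
(∂r/∂θ < 0, a stabilizing choice that also makes stiffness monotone in
activation on the ascending limb) and a small cross-term for biarticular
muscles; fibers sit at l̃ = 0.95 at the neutral pose, so the cycle sweeps the
upper ascending limb and engages passive force at stretch extremes.

Envelopes are sums of per-cycle Gaussian bursts (center/width in % of cycle)
with multiplicative lognormal amplitude jitter (σ = 0.15; the study does not
report cycle-to-cycle variability, so this is a realistic free choice exposed
in config). Under **coupled** (strength c) all muscles of a leg share a
co-contraction drive: shared burst timing weighted c against each muscle's own
gait-phase bursts, and amplitude gains correlated through a common lognormal
factor. Under **independent** every muscle draws burst timing *and* amplitude
independently each cycle (3 bursts/cycle by default). The independent world is
deliberately unstructured: it is the negative control in which a CCI should
carry no information about stiffness. Ground-truth forces use envelopes
shifted by the configured delay and scaled by the muscle's factor, so the
delay genuinely exists in the synthetic mechanics and is recoverable by
cross-correlation.

What a green end-to-end test establishes — and what it does not: the synthetic
world has exactly periodic kinematics, Gaussian burst envelopes, stationary
carrier noise, no motion artifacts, no crosstalk, no inter-leg phase offset,
and a ground-truth stiffness produced by the same model family the pipeline
assumes. Green tests therefore establish internal consistency and correct
implementation of every published processing rule, not validity on recorded
human data.

One structural fact about the negative control deserves emphasis: stiffness
is mechanically generated by the same activations the CCI measures, so at
joints where one antagonist pair dominates stiffness (the ankle:
tibialis anterior + triceps surae are most of K) even the unstructured world
leaves a positive within-cycle correlation of 0.5–0.7. The end-to-end contrast
is therefore evaluated at the hip, where many muscles and the exclusion of the
deep flexors (fine-wire iliacus/psoas) keep any surface pair a minority share
of joint stiffness — the same mechanism the clinical literature gives for
degraded hip CCIs. Pooled over seeds {1,2,3} and both legs, the coupled world
gives best-pair CCI1(delayed) r̄ ≈ 0.81 and the independent world ≈ 0.24
(computed by `tests/test_acceptance.py`; nothing here is asserted that the
tests do not themselves compute).

## Known limitations

- No compliant tendon, no force–velocity in stiffness, no EMG-driven
  calibration (calibrated parameters are *inputs*); no frontal/transverse
  DOFs; no ground-reaction or marker data; no moment-based or time-integrated
  CCIs.
- The two legs share kinematics and events; hemiparetic asymmetry is only
  parametric.
- Activation dynamics in the pipeline's stiffness stage run on the 101-point
  cycle grid (≈72 Hz), a coarser integration than the 1 kHz ground truth;
  the end-to-end correlation targets absorb the small difference.
- The storage-dialect reader handles the plain text header-block format, not
  binary motion-capture containers.
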