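# ccistiff — co-contraction indices vs. joint stiffness during gait

Muscle co-contraction — simultaneous activation of muscles on opposite sides
of a joint — raises joint stiffness, which stabilizes movement but is very
hard to measure or compute directly. EMG-based Co-Contraction Indices (CCIs),
by contrast, are trivial to compute in a clinic. This package implements, as a
tested end-to-end pipeline on a fully synthetic virtual subject, the analysis
needed to ask: **how well do common CCIs approximate sagittal-plane joint
stiffness trends during gait?** It is aimed at neuromuscular-biomechanics and
rehabilitation researchers who want a transparent, reproducible reference
implementation of every step.

## The quantities at the core

Two standard CCI formulations over an antagonist muscle pair, applied
pointwise with `L(t)`/`H(t)` the lower/higher envelope value at each of 101
normalized gait-cycle time points:

    CCI1(t) = (L/H)·(L + H)        (magnitude-sensitive)
    CCI2(t) = 2·L / (L + H)        (pure activity ratio, in [0, 1])

Model-based joint stiffness is the elastic response of the net joint moment to
joint position at fixed activation (not the torque–angle "quasi-stiffness"):

    K_joint = −∂M_j/∂θ_j,   M_j = Σ_i r_ij·F_i^T
    K_joint = Σ_i [ r_ij²·(∂F_i^T/∂l_i^MT) − (∂r_ij/∂θ_j)·F_i^T ]

with polynomial musculotendon-length surrogates (so moment arms
r = −∂l^MT/∂θ and their gradients are analytic) and a rigid-tendon Hill-type
muscle model (Gaussian active and exponential passive force–length, isometric
evaluation). EMG envelopes come in four variants: **basic** (40 Hz high-pass,
demean, rectify, 3.5/period low-pass, zero-phase 4th-order Butterworth,
101-point cycles, per-cycle min 0, trial max 1), **scaled** (× muscle-specific
scale factor), **delayed** (electromechanical delay, 82/93 ms per leg), and
**calibrated** (delayed × scale). Per-cycle Pearson correlations between each
CCI and K_joint are summarized by strength class (weak ≥ 0.3, moderate ≥ 0.5,
strong ≥ 0.7) and CCI1-vs-CCI2 contrasts are tested with a two-sided Wilcoxon
rank-sum at α = 0.05 (exact for small samples).

Because joint stiffness requires a calibrated musculoskeletal model, the
package ships a first-class synthetic-data module: a two-legged virtual
subject (16 muscles per leg, surface + fine-wire channels, scale factors from
a calibrated-subject table), burst-like activation envelopes with lognormal
cycle-to-cycle jitter, amplitude-modulated 40–450 Hz raw EMG at 1,000 Hz, and
a **controllable coupling** between antagonist co-activation and stiffness
(`coupled` shares burst timing and amplitude gains across muscles;
`independent` is an unstructured negative-control world).

## Worked example

Run the numbered analysis drivers (or `ccistiff run`, or stage by stage via
the `ccistiff` CLI):

    python analysis/01_simulate.py        --seed 1 --cycles 10 --coupling coupled
    python analysis/02_process_emg.py     --seed 1
    python analysis/03_joint_stiffness.py --seed 1
    python analysis/04_cci.py             --seed 1
    python analysis/05_correlate.py       --seed 1
    python analysis/06_report.py          --seed 1

`03_joint_stiffness.py` prints peak stiffness per joint, e.g.

    peak joint stiffness (N·m/rad):
    non-paretic  ankle_dorsiflexion     98.843969
                 hip_flexion            97.987318
                 knee_flexion           79.371285
    paretic      ankle_dorsiflexion    120.176260
                 hip_flexion            85.153957
                 knee_flexion           81.559562

— magnitudes around 100 N·m/rad, the range reported for hemiparetic gait.
`06_report.py` prints the best CCI1(delayed) pair per joint:

                               dof muscle_a muscle_b   r_mean     r_sd strength
    non-paretic/ankle_dorsiflexion   tibant   soleus 0.863274 0.037860   strong
           non-paretic/hip_flexion  addlong  semiten 0.845511 0.042569   strong
          non-paretic/knee_flexion  semiten   vaslat 0.811642 0.053732   strong
        paretic/ankle_dorsiflexion   tibant   soleus 0.894848 0.024007   strong
            paretic/hip_flexion      recfem  semimem 0.751282 0.072923   strong
           paretic/knee_flexion      gasmed   vaslat 0.731055 0.087372   strong

Read: with co-activation genuinely coupled to stiffness, the delayed-EMG CCI1
of classic clinical pairs (tibialis anterior–soleus, quadriceps–hamstrings)
tracks the model-based stiffness strongly within gait cycles — and the full
report table shows the same ordering observed clinically: CCI1 beats CCI2,
and the delay matters more than the scale factor (basic/scaled variants sit
near r ≈ 0.4–0.5 where delayed/calibrated reach 0.8–0.9). Under
`--coupling independent` the same pairs become uninformative (|r̄| < 0.3).

## Acceptance script

    python scripts/acceptance.py --seed 1 --out results/acceptance.json

recomputes the whole analysis from scratch at study scale — simulate a
10-cycle, 1,000 Hz, 16-muscle-per-leg trial for the given seed, process the
four EMG variants, assemble joint stiffness, enumerate admissible pairs,
compute CCIs, correlations and the best-pair report (all intermediates under
`results/acceptance_run/`) — and writes the acceptance JSON to `--out`.
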