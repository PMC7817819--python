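"""Estimate per-cycle sagittal joint stiffness from calibrated envelopes.

Calibrated (delayed, scaled) envelopes are converted to activations and fed
through the analytic rigid-tendon stiffness assembly K = r²·∂F/∂l − (∂r/∂θ)·F
for hip, knee and ankle of both legs.  Writes stiffness.csv and the per-muscle
mean contribution fractions (fractions.csv) used for the <2% pairing exclusion.
"""

import argparse

import pandas as pd

from ccistiff.cli_io import RunConfig, stage_stiffness


def main():
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--out", default="results/run")
    a = p.parse_args()
    stage_stiffness(RunConfig(seed=a.seed, out_dir=a.out), a.out)
    stiff = pd.read_csv(f"{a.out}/stiffness.csv", comment="#")
    peak = stiff.groupby(["leg", "dof"])["k_joint"].max()
    print("peak joint stiffness (N·m/rad):")
    print(peak.to_string())


if __name__ == "__main__":
    main()
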