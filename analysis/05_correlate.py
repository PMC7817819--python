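"""Correlate every CCI series with joint stiffness, cycle by cycle.

One Pearson r per gait cycle for each (leg, joint, pair, formulation, EMG
variant) cell; writes correlations.csv (per-cycle) and
correlation_summary.csv (mean, SD, strength class).
"""

import argparse

from ccistiff.cli_io import RunConfig, stage_correlate


def main():
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--out", default="results/run")
    a = p.parse_args()
    stage_correlate(RunConfig(seed=a.seed, out_dir=a.out), a.out)
    print(f"wrote correlations under {a.out}")


if __name__ == "__main__":
    main()
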