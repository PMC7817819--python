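"""Summarize which CCI formulation / EMG variant / pair tracks stiffness best.

Writes report.csv (best pair per joint × formulation × variant) and
contrasts.csv (best-CCI1 minus best-CCI2 mean correlation with the rank-sum
p value of their per-cycle r sets), then prints the CCI1(delayed) headline.
"""

import argparse

import pandas as pd

from ccistiff.cli_io import RunConfig, stage_report


def main():
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--out", default="results/run")
    a = p.parse_args()
    stage_report(RunConfig(seed=a.seed, out_dir=a.out), a.out)
    rep = pd.read_csv(f"{a.out}/report.csv", comment="#")
    best = rep[(rep.formulation == "CCI1") & (rep.variant == "delayed")]
    print("best CCI1(delayed) pair per joint:")
    print(best[["dof", "muscle_a", "muscle_b", "r_mean", "r_sd", "strength"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
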