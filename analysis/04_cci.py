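"""Compute both CCI formulations for all admissible antagonist pairs.

Surface-EMG muscles surviving the <2% stiffness-contribution filter are
classified by functional role; CCI1 = (L/H)(L+H) and CCI2 = 2L/(L+H) are
evaluated pointwise per cycle for every agonist × antagonist combination and
EMG variant.  Writes the long-format cci.csv.
"""

import argparse

import pandas as pd

from ccistiff.cli_io import RunConfig, stage_cci


def main():
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--out", default="results/run")
    a = p.parse_args()
    stage_cci(RunConfig(seed=a.seed, out_dir=a.out), a.out)
    cci = pd.read_csv(f"{a.out}/cci.csv", comment="#")
    pairs = cci.groupby(["leg", "dof"]).apply(
        lambda g: g[["muscle_a", "muscle_b"]].drop_duplicates().shape[0],
        include_groups=False,
    )
    print("admissible antagonist pairs per joint:")
    print(pairs.to_string())


if __name__ == "__main__":
    main()
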