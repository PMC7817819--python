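"""Process raw EMG into the four per-cycle envelope variants.

Reads the simulated trial from results/run/ and writes envelopes_basic.csv,
envelopes_scaled.csv, envelopes_delayed.csv and envelopes_calibrated.csv
(101-point normalized cycles; basic max = 1, per-cycle min = 0).
"""

import argparse

from ccistiff.cli_io import RunConfig, stage_process


def main():
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--out", default="results/run")
    a = p.parse_args()
    stage_process(RunConfig(seed=a.seed, out_dir=a.out), a.out)
    print(f"wrote four envelope variants under {a.out}")


if __name__ == "__main__":
    main()
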