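#!/usr/bin/env python
"""Descriptive summary of the (simulated) crossover dataset: totals per
sex, crossovers per meiosis, recombinant classes, and adjacent
inter-crossover distances — the quantities a study of this design reports
first.  Reads the TSV trio written by 01_simulate.py."""

import argparse
from pathlib import Path

from xover.data_model import read_crossover_table, summarize_dataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--prefix", type=Path, default=ROOT / "results/simulated/cc")
    ap.add_argument("--out", type=Path, default=ROOT / "results/summary.tsv")
    args = ap.parse_args()

    ds = read_crossover_table(
        args.prefix.with_suffix(".crossovers.tsv"),
        args.prefix.with_suffix(".map.tsv"),
        manifest_path=args.prefix.with_suffix(".manifest.tsv"),
    )
    s = summarize_dataset(ds)
    frame = s.to_frame()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out, sep="\t")
    print(frame.to_string())
    print(f"\ntotal crossovers: {s.total_crossovers}; "
          f"non-recombinant {100 * s.frac_nonrecombinant:.1f}%, "
          f"single {100 * s.frac_single:.1f}%, "
          f"multi {100 * s.frac_multi:.1f}%")


if __name__ == "__main__":
    main()
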