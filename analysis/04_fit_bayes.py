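#!/usr/bin/env python
"""Hierarchical Bayesian fit of the gamma-sprinkling model by
Metropolis-coupled MCMC, with sex as the meiosis-group factor and an
optional chromosome-group factor (size bins long / medium / short).

Writes posterior draws, a posterior summary table (means, quantile
intervals, 95% HPDIs) and the sex-ratio contrasts under results/bayes/.
"""

import argparse
from pathlib import Path

from xover.bayes import MCMCConfig, run_mc3
from xover.data_model import read_crossover_table
from xover.summaries import contrasts

ROOT = Path(__file__).resolve().parents[1]
GROUPINGS = {"sex": "none", "sex-bin": "size-bin", "sex-chrom": "per-chromosome"}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--prefix", type=Path, default=ROOT / "results/simulated/cc")
    ap.add_argument("--group-by", choices=list(GROUPINGS), default="sex")
    ap.add_argument("--iterations", type=int, default=5000)
    ap.add_argument("--burn-in", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=ROOT / "results/bayes/stahl_sex")
    args = ap.parse_args()

    ds = read_crossover_table(
        args.prefix.with_suffix(".crossovers.tsv"),
        args.prefix.with_suffix(".map.tsv"),
        manifest_path=args.prefix.with_suffix(".manifest.tsv"),
        chromosome_grouping=GROUPINGS[args.group_by],
    )
    cfg = MCMCConfig(iterations=args.iterations, burn_in=args.burn_in,
                     seed=args.seed)
    post = run_mc3(ds, cfg)
    post.save(args.out, extra_meta={"seed": args.seed, "group_by": args.group_by})

    summary = post.summary()
    summary.to_csv(args.out.with_suffix(".posterior_summary.tsv"),
                   sep="\t", index=False)
    ctr = contrasts(post)
    ctr.to_csv(args.out.with_suffix(".contrasts.tsv"), sep="\t", index=False)
    print(summary.to_string(index=False))
    print()
    print(ctr.to_string(index=False))
    print(f"\nacceptance: {post.block_acceptance}; "
          f"swap acceptance: {post.swap_acceptance.round(2).tolist()}")


if __name__ == "__main__":
    main()
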