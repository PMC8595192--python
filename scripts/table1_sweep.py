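#!/usr/bin/env python
"""Full 31-parameter sensitivity sweep (341 healing-year simulations).

This is the long-running companion to the bookkeeping checks in the test
suite: at production resolution it takes on the order of hours on one CPU
(use --workers and --cache-dir to parallelize and resume).  It writes the
raw per-run summaries and the z-score sensitivity table, whose expected
qualitative outcome is that the equilibrium collagen concentration
(rho_bar) carries the largest total score, with the fibroblast and
myofibroblast apoptosis rates, the body-force constant R, and the
signaling secretion rate k_c also near the top.

Usage:  python scripts/table1_sweep.py --out results/sweep [--fast]
"""

import argparse
from pathlib import Path

from morphoscar import NumericsConfig
from morphoscar.config import atomic_write_text
from morphoscar.sensitivity import SweepSpec, run_sweep, sensitivity_scores


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--workers", type=int, default=1)
    ap.add_argument("--cache-dir", type=Path, default=None)
    ap.add_argument("--fast", action="store_true",
                    help="reduced resolution (n=100 elements, dt=0.25)")
    args = ap.parse_args()

    if args.fast:
        numerics = NumericsConfig(n_elements=100, dt=0.25, dt_early=0.05)
    else:
        numerics = NumericsConfig()
    spec = SweepSpec(numerics=numerics)
    df = run_sweep(spec, n_jobs=args.workers, cache_dir=args.cache_dir)
    args.out.mkdir(parents=True, exist_ok=True)
    atomic_write_text(args.out / "raw_summaries.csv", df.to_csv(index=False))
    table = sensitivity_scores(df)
    atomic_write_text(args.out / "sensitivity.csv", table.to_csv())
    print(table.sort_values("S_total", ascending=False).to_string())


if __name__ == "__main__":
    main()
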