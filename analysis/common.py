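"""Shared argument handling for the analysis drivers."""

import argparse
from pathlib import Path

from ckdcost.synthetic import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def parse_args(description: str) -> tuple[SimConfig, Path]:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--n", type=int, default=4_000, help="cohort size")
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--out", type=Path, default=RESULTS)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    return SimConfig(n_persons=args.n, seed=args.seed), args.out
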