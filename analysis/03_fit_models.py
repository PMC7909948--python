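#!/usr/bin/env python
"""Fit state-dependent models for every unit and summarize the population.

Usage: python analysis/03_fit_models.py --data <dir> --seed <int> --out <dir>

Loads the session containers written by 01_simulate.py, runs the full
cross-validated model comparison (full / task-only / pupil-only / null) per
unit, computes unique variance, significance and modulation indices, and
writes <out>/unit_results.csv plus <out>/population.json. Ground truth is
not consulted.
"""

import argparse
import json
from pathlib import Path

import pupiltask as pt
from pupiltask.pipeline import FLOAT_FMT, analyze_population


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=str, required=True)
    ap.add_argument("--seed", type=int, required=True)
    ap.add_argument("--out", type=str, required=True)
    ap.add_argument("--n-iter", type=int, default=2000,
                    help="bootstrap/permutation iterations for population stats")
    args = ap.parse_args()

    sessions = []
    for d in sorted(Path(args.data).iterdir()):
        if (d / "signals.h5").exists():
            sessions.append((pt.load_session(d), None))
    if not sessions:
        raise SystemExit(f"no session containers found in {args.data}")

    res = analyze_population(sessions, seed=args.seed, n_iter=args.n_iter)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    res["units"].to_csv(out / "unit_results.csv", index=False, float_format=FLOAT_FMT)
    with open(out / "population.json", "w") as f:
        json.dump(res["population"], f, indent=1, sort_keys=True, default=str)
    print(json.dumps(res["population"], indent=1, sort_keys=True, default=str))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
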