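#!/usr/bin/env python
"""Score go/no-go behavior for every session in a data directory.

Usage: python analysis/02_behavior.py --data <dir> --out <dir>

Reads each session container (sub-directory with signals.h5) written by
01_simulate.py and writes <out>/behavior.csv with one row per active block:
hits, misses, FAs, CRs, hit rate, false-alarm rate and d'.
"""

import argparse
from pathlib import Path

import pandas as pd

import pupiltask as pt
from pupiltask.pipeline import FLOAT_FMT


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=str, required=True)
    ap.add_argument("--out", type=str, required=True)
    args = ap.parse_args()

    rows = []
    for d in sorted(Path(args.data).iterdir()):
        if not (d / "signals.h5").exists():
            continue
        session = pt.load_session(d)
        beh = pt.score_session(session)
        beh.insert(0, "site", session.meta.get("site", d.name))
        rows.append(beh)
    if not rows:
        raise SystemExit(f"no session containers found in {args.data}")
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(out / "behavior.csv", index=False, float_format=FLOAT_FMT)
    print(table.to_string(index=False))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
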