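#!/usr/bin/env python
"""Simulate a synthetic population and write session containers + truth.json.

Usage: python analysis/01_simulate.py --config <yaml> --seed <int> --out <dir>

The YAML config may set any GenerativeConfig field (e.g. trials_per_block,
n_units, hr, far, pupil_active_shift) plus `n_sites` (default 8). Omitting
--config uses the study-condition defaults. One sub-directory per site is
written (signals.h5, epochs.csv, meta.json) alongside truth.json with the
generating parameters of every unit.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import yaml

import pupiltask as pt


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", type=str, default=None)
    ap.add_argument("--seed", type=int, required=True)
    ap.add_argument("--out", type=str, required=True)
    args = ap.parse_args()

    raw = {}
    if args.config:
        with open(args.config) as f:
            raw = yaml.safe_load(f) or {}
    n_sites = int(raw.pop("n_sites", 8))
    valid = {f.name for f in dataclasses.fields(pt.GenerativeConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise SystemExit(f"unknown config keys: {sorted(unknown)}")
    cfg = pt.GenerativeConfig(**raw)
    cfg.validate()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    pops = pt.generate_population(n_sites, seed=args.seed, base_config=cfg)
    truths = {}
    for session, truth in pops:
        site = session.meta["site"]
        pt.save_session(session, out / site)
        truths[site] = truth.summary()
    with open(out / "truth.json", "w") as f:
        json.dump(truths, f, indent=1, sort_keys=True)
    print(f"wrote {n_sites} sessions to {out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
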