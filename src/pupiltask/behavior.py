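"""Signal-detection scoring of go/no-go behavior: HR, FAR and d' per block.

A trial is a sequence of reference noises followed (usually) by a target tone.
A lick inside the response window 0.1-1.5 s after target onset is a hit; a
lick before the window is a false alarm (FA); no lick with a target presented
is a miss; each completed reference presentation without a lick contributes a
correct rejection (CR).  HR = hits/(hits+misses), FAR = FAs/(FAs+CRs), and
sensitivity d' = z(HR) - z(FAR) after clipping rates away from 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .session import Session, _parse_epochs, _EPS

TARGET_WINDOW = (0.1, 1.5)


@dataclass
class BehaviorSummary:
    """Per-block trial counts and detection metrics."""

    block: str
    hits: int = 0
    misses: int = 0
    fas: int = 0
    crs: int = 0
    hr: float = np.nan
    far: float = np.nan
    dprime: float = np.nan


def score_trial(first_lick, target_onset, window=TARGET_WINDOW) -> str:
    """Classify one trial outcome from the first lick and target onset times.

    A lick after the window end with no earlier lick counts as a miss.
    ``target_onset`` may be None only for trials terminated by an early lick
    (scored FA).
    """
    if first_lick is None:
        if target_onset is None:
            raise ValueError("trial with neither lick nor target cannot be scored")
        return "MISS"
    if target_onset is None:
        return "FA"
    lo, hi = target_onset + window[0], target_onset + window[1]
    if lo - _EPS <= first_lick <= hi + _EPS:
        return "HIT"
    if first_lick < lo:
        return "FA"
    return "MISS"


def compute_rates(summary: BehaviorSummary) -> tuple[float, float]:
    """Exact HR and FAR ratios (no clipping)."""
    if summary.hits + summary.misses == 0:
        raise ValueError("no target trials: HR undefined (hits+misses == 0)")
    if summary.fas + summary.crs == 0:
        raise ValueError("no reference outcomes: FAR undefined (FAs+CRs == 0)")
    hr = summary.hits / (summary.hits + summary.misses)
    far = summary.fas / (summary.fas + summary.crs)
    return hr, far


def compute_dprime(hr: float, far: float, n_target: int, n_ref: int) -> float:
    """d' = z(HR) - z(FAR) with rates clipped to [1/(2n), 1 - 1/(2n)].

    The clipping keeps d' finite for perfect rates; n is the relevant trial
    count for each rate (targets for HR, references for FAR).
    """
    if not (0 <= hr <= 1 and 0 <= far <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_target < 1 or n_ref < 1:
        raise ValueError("counts must be >= 1")
    hr_c = float(np.clip(hr, 0.5 / n_target, 1 - 0.5 / n_target))
    far_c = float(np.clip(far, 0.5 / n_ref, 1 - 0.5 / n_ref))
    return float(norm.ppf(hr_c) - norm.ppf(far_c))


def score_session(session: Session) -> pd.DataFrame:
    """Score every active block of a session from its lick/target epochs.

    Returns one row per active block: session, block, hits, misses, FAs, CRs,
    HR, FAR, dprime.  CRs count completed (un-licked) reference presentations.
    """
    blocks, trials, refs, targets, outcomes, licks = _parse_epochs(session.epochs)
    lick_times = sorted(s for s, e in licks)
    tgt_by_trial = {}
    for ts, te in targets:
        for tid, s, e in trials:
            if s - _EPS <= ts < e + _EPS:
                tgt_by_trial[tid] = ts
                break
    rows = []
    for lab, ordinal, active, bs, be in blocks:
        if not active:
            continue
        summ = BehaviorSummary(block=ordinal)
        for tid, s, e in trials:
            if not (bs - _EPS <= s < be + _EPS):
                continue
            tl = [t for t in lick_times if s - _EPS <= t < e + _EPS]
            first_lick = tl[0] if tl else None
            tgt = tgt_by_trial.get(tid)
            outcome = score_trial(first_lick, tgt)
            if outcome == "HIT":
                summ.hits += 1
            elif outcome == "MISS":
                summ.misses += 1
            elif outcome == "FA":
                summ.fas += 1
            # completed references without a lick -> CRs
            for _stim, rs, re_ in refs:
                if s - _EPS <= rs < e + _EPS and re_ <= e + _EPS:
                    if first_lick is None or first_lick > re_ - _EPS:
                        summ.crs += 1
        if summ.hits + summ.misses > 0 and summ.fas + summ.crs > 0:
            summ.hr, summ.far = compute_rates(summ)
            summ.dprime = compute_dprime(
                summ.hr, summ.far, summ.hits + summ.misses, summ.fas + summ.crs
            )
        rows.append(
            dict(session=session.meta.get("session_id", ""), block=summ.block,
                 hits=summ.hits, misses=summ.misses, fas=summ.fas, crs=summ.crs,
                 hr=summ.hr, far=summ.far, dprime=summ.dprime)
        )
    return pd.DataFrame(rows)
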