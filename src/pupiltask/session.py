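"""Session data model, container I/O, and preprocessing.

A :class:`Session` bundles the binned signals of one recording: per-unit spike
rates and pupil diameter on a common 20 samples/s grid, plus an epochs table
marking behavior blocks, trials, reference/target sound events, licks, and
trial outcomes.  All downstream analysis consumes the per-presentation
reference responses extracted here (:func:`extract_reference_responses`).

Time conventions
----------------
Epochs are in seconds as half-open intervals ``[start, end)``.  Bins are
0-based; a bin belongs to an epoch iff its left edge lies in the interval.
Reference stimuli are 0.75 s long (15 bins at 20 Hz) with 0.7 s gaps.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

FS = 20.0
BIN = 1.0 / FS
REF_DUR = 0.75
ISI = 0.7
PUPIL_LAG = 0.75
#: spontaneous-rate windows: pre-trial baseline length and post-offset blanking
PRETRIAL_SILENCE = 0.35
OFFSET_BLANK = 0.2

_EPS = 1e-9

_BLOCK_RE = re.compile(r"^(PASSIVE|ACTIVE)_BLOCK:(\d+)$")
_TRIAL_RE = re.compile(r"^TRIAL:(\d+)$")
_REF_RE = re.compile(r"^REFERENCE:(.+)$")
OUTCOMES = ("HIT", "MISS", "FA", "CR")


class SessionFormatError(ValueError):
    """A required array/table is missing or malformed in the session container."""


class SessionValidationError(ValueError):
    """A Session violates its structural invariants."""


def bin_slice(start: float, end: float, fs: float = FS) -> slice:
    """Bins whose left edge lies in [start, end)."""
    i0 = int(np.ceil(start * fs - _EPS))
    i1 = int(np.ceil(end * fs - _EPS))
    return slice(max(i0, 0), max(i1, 0))


@dataclass
class Session:
    """One recording: unit rates, pupil, epochs and metadata on one bin grid."""

    rate: np.ndarray          # (n_units, n_bins) spikes/s
    pupil: np.ndarray         # (n_bins,) raw diameter units
    epochs: pd.DataFrame      # columns: label, start, end (seconds)
    meta: dict                # session_id, animal, area, unit_ids, ...
    fs: float = FS

    @property
    def n_units(self) -> int:
        return self.rate.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rate.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins / self.fs

    def validate(self) -> None:
        if self.rate.ndim != 2:
            raise SessionValidationError("rate must be a (units x time) matrix")
        if self.pupil.shape != (self.n_bins,):
            raise SessionValidationError(
                f"pupil length {self.pupil.shape} does not match rate bins {self.n_bins}"
            )
        required = {"label", "start", "end"}
        if not required.issubset(self.epochs.columns):
            raise SessionFormatError(f"epochs table missing columns {required - set(self.epochs.columns)}")
        ep = self.epochs
        if (ep["end"] < ep["start"] - _EPS).any():
            raise SessionValidationError("epoch with end < start")
        if (ep["start"] < -_EPS).any() or (ep["end"] > self.duration + _EPS).any():
            bad = ep[(ep["start"] < -_EPS) | (ep["end"] > self.duration + _EPS)]
            raise SessionValidationError(
                f"epochs outside signal extent [0, {self.duration:.2f}]: {bad['label'].tolist()[:5]}"
            )
        # blocks tile the session without overlap
        blocks = ep[ep["label"].str.match(_BLOCK_RE)].sort_values("start")
        if len(blocks):
            starts = blocks["start"].to_numpy()
            ends = blocks["end"].to_numpy()
            if (starts[1:] < ends[:-1] - _EPS).any():
                raise SessionValidationError("overlapping behavior blocks")
            if (np.abs(starts[1:] - ends[:-1]) > _EPS).any():
                raise SessionValidationError("gap between behavior blocks")
            if abs(starts[0]) > _EPS or abs(ends[-1] - self.duration) > _EPS:
                raise SessionValidationError("blocks do not tile the session extent")
        # every trial carries exactly one outcome
        trials = ep[ep["label"].str.match(_TRIAL_RE)]
        outc = ep[ep["label"].isin(OUTCOMES)]
        for _, tr in trials.iterrows():
            n = int(((outc["start"] >= tr["start"] - _EPS) & (outc["end"] <= tr["end"] + _EPS)).sum())
            if n != 1:
                raise SessionValidationError(
                    f"trial {tr['label']} carries {n} outcome labels (expected 1)"
                )


def save_session(session: Session, path) -> None:
    """Write the documented container: signals.h5 + epochs.csv + meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "signals.h5", "w") as f:
        f.create_dataset("rate", data=np.asarray(session.rate, dtype=np.float64))
        f.create_dataset("pupil", data=np.asarray(session.pupil, dtype=np.float64))
        f.attrs["fs"] = session.fs
    ep = session.epochs.copy()
    ep["start"] = ep["start"].map(lambda v: f"{v:.6f}")
    ep["end"] = ep["end"].map(lambda v: f"{v:.6f}")
    ep[["label", "start", "end"]].to_csv(path / "epochs.csv", index=False)
    with open(path / "meta.json", "w") as f:
        json.dump(session.meta, f, indent=1, sort_keys=True)


def load_session(path) -> Session:
    """Read a session container written by :func:`save_session` and validate it."""
    path = Path(path)
    sig = path / "signals.h5"
    if not sig.exists():
        raise SessionFormatError(f"missing signals.h5 in {path}")
    with h5py.File(sig, "r") as f:
        if "rate" not in f or "pupil" not in f:
            missing = {"rate", "pupil"} - set(f.keys())
            raise SessionFormatError(f"signals.h5 missing dataset(s) {missing}")
        rate = f["rate"][...]
        pupil = f["pupil"][...]
        fs = float(f.attrs.get("fs", FS))
    epf = path / "epochs.csv"
    if not epf.exists():
        raise SessionFormatError(f"missing epochs.csv in {path}")
    epochs = pd.read_csv(epf)
    mf = path / "meta.json"
    if not mf.exists():
        raise SessionFormatError(f"missing meta.json in {path}")
    with open(mf) as f:
        meta = json.load(f)
    session = Session(rate=rate, pupil=pupil, epochs=epochs, meta=meta, fs=fs)
    session.validate()
    return session


def lag_pupil(pupil: np.ndarray, lag: float = PUPIL_LAG, fs: float = FS) -> np.ndarray:
    """Shift the pupil trace forward by ``lag`` seconds, holding the first value.

    Accounts for the delayed relationship between pupil size and neural
    activity: the neural response at time t is paired with pupil at t - lag.
    ``lag`` must be a non-negative multiple of the bin width.
    """
    pupil = np.asarray(pupil, dtype=float)
    nlag = lag * fs
    if lag < 0 or abs(nlag - round(nlag)) > 1e-6:
        raise ValueError(f"lag {lag} s is not a non-negative multiple of the {1/fs} s bin")
    n = int(round(nlag))
    if n == 0:
        return pupil.copy()
    out = np.empty_like(pupil)
    out[:n] = pupil[0]
    out[n:] = pupil[:-n]
    return out


@dataclass
class ReferenceResponseSet:
    """Per-presentation reference responses of one session, analysis-ready.

    ``resp`` holds the observed rate of every *included* reference
    presentation (passive trials and active hit trials, never overlapping a
    target); ``r0`` is the included-mean PSTH per stimulus with the
    spontaneous rate ``s0`` subtracted, so the state-independent prediction is
    ``s0 + r0(t)``.  ``p``/``b`` are the model regressors (lagged pupil
    normalized to the session maximum; binary engagement) sampled on the same
    presentation bins.  ``table`` records every presentation including
    excluded ones with the exclusion reason.
    """

    resp: np.ndarray          # (n_units, n_pres, nb) included presentations only
    r0: np.ndarray            # (n_units, n_stim, nb) evoked PSTH above s0
    s0: np.ndarray            # (n_units,)
    p: np.ndarray             # (n_pres, nb) normalized lagged pupil regressor
    b: np.ndarray             # (n_pres,) 1 active / 0 passive
    trial_ids: np.ndarray     # (n_pres,) behavioral trial index
    stim_idx: np.ndarray      # (n_pres,) row into r0 / stims
    block_ord: np.ndarray     # (n_pres,) ordinal block label, e.g. "P1", "A1", "P2"
    mean_pupil: np.ndarray    # (n_pres,) raw-unit mean lagged pupil
    stims: list               # stimulus ids in r0 row order
    table: pd.DataFrame       # all presentations with included flag + reason
    silence_sum: np.ndarray   # (n_units, n_sil_trials) rate sums in silence bins
    silence_count: np.ndarray  # (n_sil_trials,)
    silence_trials: np.ndarray  # (n_sil_trials,) trial ids
    unit_ids: list = field(default_factory=list)
    fs: float = FS
    nb: int = int(round(REF_DUR * FS))

    @property
    def n_units(self) -> int:
        return self.resp.shape[0]

    @property
    def n_pres(self) -> int:
        return self.resp.shape[1]


def _parse_epochs(epochs: pd.DataFrame):
    blocks, trials, refs, targets, outcomes, licks = [], [], [], [], [], []
    counts = {"PASSIVE": 0, "ACTIVE": 0}
    for _, row in epochs.iterrows():
        lab = row["label"]
        m = _BLOCK_RE.match(lab)
        if m:
            counts[m.group(1)] += 1
            ordinal = ("P" if m.group(1) == "PASSIVE" else "A") + str(counts[m.group(1)])
            blocks.append((lab, ordinal, m.group(1) == "ACTIVE", row["start"], row["end"]))
            continue
        m = _TRIAL_RE.match(lab)
        if m:
            trials.append((int(m.group(1)), row["start"], row["end"]))
            continue
        m = _REF_RE.match(lab)
        if m:
            refs.append((m.group(1), row["start"], row["end"]))
            continue
        if lab == "TARGET":
            targets.append((row["start"], row["end"]))
        elif lab in OUTCOMES:
            outcomes.append((lab, row["start"], row["end"]))
        elif lab == "LICK":
            licks.append((row["start"], row["end"]))
    return blocks, trials, refs, targets, outcomes, licks


def extract_reference_responses(session: Session, lag: float = PUPIL_LAG) -> ReferenceResponseSet:
    """Extract per-presentation reference responses, PSTHs and regressors.

    Presentations from active miss/FA trials, and any presentation overlapping
    a TARGET epoch, are flagged excluded.  The spontaneous rate ``s0`` is the
    mean rate over pre-trial silence (0.35 s before trial onset) and
    inter-stimulus gaps (excluding 0.2 s after each stimulus offset to avoid
    offset responses), pooled over included trials.
    """
    fs = session.fs
    nb = int(round(REF_DUR * fs))
    blocks, trials, refs, targets, outcomes, _ = _parse_epochs(session.epochs)
    if not blocks or not trials or not refs:
        raise SessionFormatError("epochs table lacks blocks, trials or reference events")

    plag = lag_pupil(session.pupil, lag=lag, fs=fs)
    pmax = float(np.max(session.pupil))
    p_reg = plag / pmax if pmax > 0 else plag.copy()

    def containing(intervals, t):
        for item in intervals:
            if item[-2] - _EPS <= t < item[-1] + _EPS:
                return item
        return None

    trial_outcome = {}
    for lab, s, e in outcomes:
        tr = containing(trials, s)
        if tr is not None:
            trial_outcome[tr[0]] = lab

    rows = []
    for stim, s, e in refs:
        tr = containing(trials, s)
        blk = containing(blocks, s)
        if tr is None or blk is None:
            raise SessionValidationError(f"reference at {s:.2f}s outside any trial/block")
        outcome = trial_outcome.get(tr[0], "CR")
        active = blk[2]
        sl = bin_slice(s, e, fs)
        reason = ""
        if active and outcome != "HIT":
            reason = "active_nonhit"
        if any(ts < e - _EPS and te > s + _EPS for ts, te in targets):
            reason = (reason + "+target_overlap") if reason else "target_overlap"
        if sl.stop - sl.start != nb or sl.stop > session.n_bins:
            reason = (reason + "+truncated") if reason else "truncated"
        rows.append(
            dict(stim=stim, trial=tr[0], block=blk[0], ordinal=blk[1], active=active,
                 outcome=outcome, start=s, end=e, bin0=sl.start,
                 mean_pupil=float(np.mean(plag[sl])) if sl.stop <= session.n_bins else np.nan,
                 included=reason == "", reason=reason)
        )
    table = pd.DataFrame(rows)

    # drop stimuli with zero included presentations
    for stim, grp in table.groupby("stim"):
        if not grp["included"].any():
            warnings.warn(f"stimulus {stim} has no included presentations; excluded")
    inc = table[table["included"]].reset_index(drop=True)
    if inc.empty:
        raise SessionValidationError("no included reference presentations")
    stims = sorted(inc["stim"].unique())
    stim_row = {s: i for i, s in enumerate(stims)}

    n_units = session.n_units
    n_pres = len(inc)
    resp = np.empty((n_units, n_pres, nb))
    p = np.empty((n_pres, nb))
    for i, row in inc.iterrows():
        sl = slice(int(row["bin0"]), int(row["bin0"]) + nb)
        resp[:, i, :] = session.rate[:, sl]
        p[i, :] = p_reg[sl]
    b = inc["active"].to_numpy().astype(float)
    trial_ids = inc["trial"].to_numpy()
    stim_idx = np.array([stim_row[s] for s in inc["stim"]])
    block_ord = inc["ordinal"].to_numpy()
    mean_pupil = inc["mean_pupil"].to_numpy()

    # spontaneous-rate windows per included trial
    included_trials = sorted(inc["trial"].unique())
    trial_by_id = {t[0]: t for t in trials}
    sil_sum = []
    sil_cnt = []
    sil_tid = []
    ref_by_trial = {}
    for stim, s, e in refs:
        tr = containing(trials, s)
        if tr is not None:
            ref_by_trial.setdefault(tr[0], []).append((s, e))
    tgt_starts = sorted(ts for ts, te in targets)
    for tid in included_trials:
        t0, _, _t2 = trial_by_id[tid][0], trial_by_id[tid][1], trial_by_id[tid][2]
        tstart = trial_by_id[tid][1]
        windows = [(max(tstart - PRETRIAL_SILENCE, 0.0), tstart)]
        evs = sorted(ref_by_trial.get(tid, []))
        for (s1, e1), (s2, _e2) in zip(evs[:-1], evs[1:]):
            windows.append((e1 + OFFSET_BLANK, s2))
        if evs:
            nxt = [ts for ts in tgt_starts if ts > evs[-1][1] - _EPS and ts < trial_by_id[tid][2]]
            if nxt:
                windows.append((evs[-1][1] + OFFSET_BLANK, nxt[0]))
        ssum = np.zeros(n_units)
        cnt = 0
        for ws, we in windows:
            sl = bin_slice(ws, we, fs)
            sl = slice(sl.start, min(sl.stop, session.n_bins))
            if sl.stop > sl.start:
                ssum += session.rate[:, sl].sum(axis=1)
                cnt += sl.stop - sl.start
        if cnt > 0:
            sil_sum.append(ssum)
            sil_cnt.append(cnt)
            sil_tid.append(tid)
    silence_sum = np.array(sil_sum).T if sil_sum else np.zeros((n_units, 0))
    silence_count = np.array(sil_cnt, dtype=float)
    silence_trials = np.array(sil_tid)

    s0 = (silence_sum.sum(axis=1) / silence_count.sum()) if silence_count.sum() > 0 else np.zeros(n_units)

    r0 = np.empty((n_units, len(stims), nb))
    for s, row_i in stim_row.items():
        mask = stim_idx == row_i
        r0[:, row_i, :] = resp[:, mask, :].mean(axis=1) - s0[:, None]

    return ReferenceResponseSet(
        resp=resp, r0=r0, s0=s0, p=p, b=b, trial_ids=trial_ids, stim_idx=stim_idx,
        block_ord=block_ord, mean_pupil=mean_pupil, stims=stims, table=table,
        silence_sum=silence_sum, silence_count=silence_count, silence_trials=silence_trials,
        unit_ids=list(session.meta.get("unit_ids", range(n_units))), fs=fs, nb=nb,
    )


def label_pupil_trials(refset: ReferenceResponseSet) -> np.ndarray:
    """Median-split included presentations into 'large'/'small' pupil classes.

    The split is over per-presentation means of the lagged pupil; ties go to
    'small' so the labeling is deterministic.
    """
    means = refset.mean_pupil
    if np.allclose(means, means[0]):
        warnings.warn("constant pupil: all presentations labeled 'small'")
        return np.array(["small"] * len(means))
    med = float(np.median(means))
    return np.where(means > med, "large", "small")
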