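"""Synthetic go/no-go sessions with stored ground truth.

Sessions emulate the statistical structure the analysis assumes: alternating
passive/active blocks; trials of 2-5 reference noises (0.75 s, 0.7 s gaps)
followed by a target with a 0.1-1.5 s response window; flat-hazard trial
lengths; pupil that is larger in active blocks, generated as a block-dependent
baseline plus zero-mean Ornstein-Uhlenbeck noise and a trial-onset dilation
transient (larger when engaged); spike rates from the state-dependent model
with known coefficients plus count noise; and hit/miss/FA outcomes at
configurable rates.

Identifiability: the analysis estimates r0(t) as the session-average PSTH,
which absorbs any mean state modulation.  The generator therefore fixes the
offsets d0, g0 so the mean DC and gain terms over included reference bins
equal 1 — the stored true PSTH then coincides with the average response and
the remaining coefficients (dp, db, gp, gb) are recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .session import FS, ISI, REF_DUR, Session, lag_pupil
from .statemodel import DEFAULT_CONSTANTS, SigmoidConstants, StateModelParams
from .modulation import compute_mi

EFFECT_TYPES = ("task", "pupil", "both", "none")


@dataclass
class GenerativeConfig:
    """All knobs of the session generator; durations on the 0.05 s grid."""

    blocks: tuple = ("passive", "active", "passive")
    trials_per_block: int = 60
    hazard: float = 1.0 / 3.0          # flat hazard over 2-5 references
    n_refs_min: int = 2
    n_refs_max: int = 5
    n_stims: int = 30
    fs: float = FS
    ref_dur: float = REF_DUR
    isi: float = ISI
    target_dur: float = 0.75
    resp_window: tuple = (0.1, 1.5)
    iti_mean: float = 2.5
    iti_jitter: float = 0.5
    # pupil (arbitrary diameter units)
    pupil_passive_baseline: float = 30.0
    pupil_active_shift: float = 15.0
    pupil_ou_tau: float = 20.0
    pupil_ou_sigma: float = 5.0
    dilation_amp_active: float = 10.0
    dilation_amp_passive: float = 2.0
    dilation_peak: float = 1.0         # seconds after trial onset
    miss_small_pupil: bool = False
    # behavior
    hr: float = 0.85
    far: float = 0.05                  # per reference presentation
    # units
    n_units: int = 4
    unit_effects: tuple | None = None  # per-unit effect types; drawn if None
    effect_proportions: tuple = (0.2, 0.15, 0.15, 0.5)  # task, pupil, both, none
    coef_min: float = 0.3
    coef_max: float = 0.7
    pupil_coef_scale: float = 1.0      # scales dp, gp (effect-size-ratio sweeps)
    task_coef_scale: float = 1.0       # scales db, gb
    coef_sign: str = "random"          # 'random' | 'positive' (aligned effects)
    psth_amp_min: float = 10.0
    psth_amp_max: float = 40.0
    s0_min: float = 3.0
    s0_max: float = 8.0
    noise: str = "poisson"             # 'poisson' | 'gaussian' | 'none'
    gaussian_sd: float = 2.0
    constants: SigmoidConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)
    area: str = "A1"

    def validate(self) -> None:
        bin_w = 1.0 / self.fs
        for name in ("ref_dur", "isi", "target_dur", "iti_mean", "iti_jitter"):
            v = getattr(self, name)
            if abs(v / bin_w - round(v / bin_w)) > 1e-6:
                raise ValueError(f"{name}={v} is not on the {bin_w} s bin grid")
        if self.noise not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.coef_sign not in ("random", "positive"):
            raise ValueError(f"unknown coef_sign {self.coef_sign!r}")


@dataclass
class UnitTruth:
    """Generating parameters of one synthetic unit."""

    params: StateModelParams
    s0: float
    psth: np.ndarray          # (n_stims, nb) evoked rate above s0, >= 0
    effect: str
    mi_ap: float = np.nan     # analytic MI from the noiseless rates
    mi_ls: float = np.nan


@dataclass
class GroundTruth:
    """Everything needed to oracle-check the pipeline on a synthetic session."""

    units: list
    constants: SigmoidConstants
    noiseless_rate: np.ndarray    # (n_units, n_bins)
    p_reg: np.ndarray             # (n_bins,) lagged, max-normalized pupil
    b: np.ndarray                 # (n_bins,) engagement indicator
    included_bins: np.ndarray     # (n_bins,) bool: included reference bins
    seed: int = 0

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "units": [
                {
                    "effect": u.effect,
                    "s0": u.s0,
                    "params": vars(u.params),
                    "mi_ap": u.mi_ap,
                    "mi_ls": u.mi_ls,
                }
                for u in self.units
            ],
        }


def _gamma_kernel(peak: float, fs: float, dur: float = 6.0) -> np.ndarray:
    """Gamma-shaped dilation kernel with unit peak amplitude."""
    shape = 3.0
    scale = peak / (shape - 1.0)
    t = np.arange(int(dur * fs)) / fs
    k = t ** (shape - 1) * np.exp(-t / scale)
    return k / k.max()


def generate_pupil(n_bins: int, active_bin: np.ndarray, trial_onset_bins: np.ndarray,
                   trial_amp: np.ndarray, config: GenerativeConfig,
                   seed: int) -> np.ndarray:
    """Pupil trace: block baseline + zero-mean OU noise + trial-onset dilations.

    With zero OU noise and zero transient amplitudes the trace is exactly
    piecewise constant at the block baselines.  Strictly positive.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / config.fs
    mu = config.pupil_passive_baseline + config.pupil_active_shift * active_bin
    z = np.zeros(n_bins)
    a = 1.0 - dt / config.pupil_ou_tau
    noise_scale = config.pupil_ou_sigma * np.sqrt(2 * dt / config.pupil_ou_tau)
    eps = rng.normal(size=n_bins)
    for t in range(1, n_bins):
        z[t] = a * z[t - 1] + noise_scale * eps[t]
    dil = np.zeros(n_bins)
    kern = _gamma_kernel(config.dilation_peak, config.fs)
    for onset, amp in zip(trial_onset_bins, trial_amp):
        if amp == 0:
            continue
        end = min(onset + len(kern), n_bins)
        dil[onset:end] += amp * kern[: end - onset]
    return np.maximum(mu + z + dil, 1.0)


def _sample_psths(rng, n_stims: int, nb: int, amp: float) -> np.ndarray:
    """Smooth, non-negative per-stimulus evoked PSTH shapes."""
    knots = rng.uniform(0, amp, size=(n_stims, 5))
    x_k = np.linspace(0, nb - 1, 5)
    x = np.arange(nb)
    return np.vstack([np.interp(x, x_k, k) for k in knots])


def _sample_coefs(rng, effect: str, lo: float, hi: float,
                  pupil_scale: float = 1.0, task_scale: float = 1.0,
                  sign: str = "random") -> dict:
    def draw():
        s = rng.choice([-1.0, 1.0]) if sign == "random" else 1.0
        return float(rng.uniform(lo, hi) * s)

    c = dict(dp=0.0, db=0.0, gp=0.0, gb=0.0)
    if effect in ("pupil", "both"):
        c["dp"], c["gp"] = pupil_scale * draw(), pupil_scale * draw()
    if effect in ("task", "both"):
        c["db"], c["gb"] = task_scale * draw(), task_scale * draw()
    return c


def generate_session(config: GenerativeConfig, seed: int = 0
                     ) -> tuple[Session, GroundTruth]:
    """Build one synthetic session and its ground truth.

    Deterministic given (config, seed).  All epoch times are integer bins
    divided by the bin rate, so the session container round-trips exactly.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    fs = config.fs
    nb = int(round(config.ref_dur * fs))
    isi_b = int(round(config.isi * fs))
    tgt_b = int(round(config.target_dur * fs))
    rw_end_b = int(round(config.resp_window[1] * fs))

    epochs = []          # (label, start_bin, end_bin)
    trial_onsets, trial_amp_active = [], []
    pres = []            # per reference presentation bookkeeping
    trial_id = 0
    cursor = 0
    block_info = []
    counts = {"passive": 0, "active": 0}
    pad = int(round(config.iti_mean * fs))

    for btype in config.blocks:
        counts[btype] += 1
        blab = ("ACTIVE_BLOCK:" if btype == "active" else "PASSIVE_BLOCK:") + str(counts[btype])
        ordinal = ("A" if btype == "active" else "P") + str(counts[btype])
        bstart = cursor
        active = btype == "active"
        for _ in range(config.trials_per_block):
            iti = config.iti_mean + rng.uniform(-config.iti_jitter, config.iti_jitter)
            cursor += int(round(iti * fs))
            tstart = cursor
            n_refs = config.n_refs_min
            while n_refs < config.n_refs_max and rng.random() >= config.hazard:
                n_refs += 1
            outcome = "CR"
            lick_bin = None
            ref_rows = []
            t = tstart
            ended_early = False
            for i in range(n_refs):
                stim = int(rng.integers(config.n_stims))
                ref_rows.append((stim, t, t + nb))
                if active and rng.random() < config.far:
                    outcome = "FA"
                    lick_bin = t + int(rng.integers(1, nb))
                    t = t + nb
                    ended_early = True
                    break
                t = t + nb + isi_b
            if not ended_early:
                tgt_start = t
                epochs_target = (tgt_start, tgt_start + tgt_b)
                t = tgt_start + rw_end_b
                if active:
                    if rng.random() < config.hr:
                        outcome = "HIT"
                        lick_bin = tgt_start + int(rng.integers(
                            int(round(config.resp_window[0] * fs)) + 1, rw_end_b - 3))
                    else:
                        outcome = "MISS"
            else:
                epochs_target = None
                t = max(lick_bin + int(round(0.3 * fs)), ref_rows[-1][2])
            tend = t
            epochs.append((f"TRIAL:{trial_id}", tstart, tend))
            for stim, rs, re_ in ref_rows:
                epochs.append((f"REFERENCE:stim{stim:02d}", rs, re_))
            if epochs_target is not None:
                epochs.append(("TARGET", *epochs_target))
            if lick_bin is not None:
                epochs.append(("LICK", lick_bin, lick_bin + 1))
            epochs.append((outcome, tstart, tend))
            trial_onsets.append(tstart)
            amp = config.dilation_amp_active if active else config.dilation_amp_passive
            if config.miss_small_pupil and outcome == "MISS":
                amp = config.dilation_amp_passive
            trial_amp_active.append(amp)
            included = (not active) or outcome == "HIT"
            for stim, rs, re_ in ref_rows:
                pres.append(dict(stim=stim, bin0=rs, trial=trial_id, active=active,
                                 ordinal=ordinal, included=included))
            cursor = tend
            trial_id += 1
        cursor += pad
        block_info.append((blab, bstart, cursor, active))
    n_bins = cursor

    active_bin = np.zeros(n_bins)
    for blab, bs, be, act in block_info:
        if act:
            active_bin[bs:be] = 1.0
    pupil = generate_pupil(n_bins, active_bin, np.array(trial_onsets),
                           np.array(trial_amp_active), config,
                           seed=int(rng.integers(2 ** 31)))
    p_reg = lag_pupil(pupil, fs=fs) / pupil.max()

    # included reference bins and regressor means for the neutral offsets
    inc_bins = np.zeros(n_bins, dtype=bool)
    for pr in pres:
        if pr["included"]:
            inc_bins[pr["bin0"]:pr["bin0"] + nb] = True
    p_bar = float(p_reg[inc_bins].mean())
    b_bar = float(active_bin[inc_bins].mean())

    effects = config.unit_effects
    if effects is None:
        effects = tuple(rng.choice(EFFECT_TYPES, size=config.n_units,
                                   p=config.effect_proportions))
    if len(effects) != config.n_units:
        raise ValueError("unit_effects length must match n_units")

    constants = config.constants
    units = []
    noiseless = np.empty((config.n_units, n_bins))
    rate = np.empty((config.n_units, n_bins))
    # stimulus-evoked trace is shared across state paths: build per unit
    tgt_epochs = [(s, e) for lab, s, e in epochs if lab == "TARGET"]
    for u in range(config.n_units):
        eff = str(effects[u])
        c = _sample_coefs(rng, eff, config.coef_min, config.coef_max,
                          pupil_scale=config.pupil_coef_scale,
                          task_scale=config.task_coef_scale,
                          sign=config.coef_sign)
        s0 = float(rng.uniform(config.s0_min, config.s0_max))
        amp = float(rng.uniform(config.psth_amp_min, config.psth_amp_max))
        psth = _sample_psths(rng, config.n_stims, nb, amp)
        d0 = 1.0 - c["dp"] * p_bar - c["db"] * b_bar
        g0 = 1.0 - c["gp"] * p_bar - c["gb"] * b_bar
        params = StateModelParams(d0=d0, dp=c["dp"], db=c["db"],
                                  g0=g0, gp=c["gp"], gb=c["gb"])
        evoked = np.zeros(n_bins)
        for pr in pres:
            evoked[pr["bin0"]:pr["bin0"] + nb] = psth[pr["stim"]]
        tgt_resp = psth.mean(axis=0)
        for ts, te in tgt_epochs:
            evoked[ts:te] = tgt_resp[: te - ts]
        xd = params.d0 + params.dp * p_reg + params.db * active_bin
        xg = params.g0 + params.gp * p_reg + params.gb * active_bin
        nl = s0 * constants.f(xd) + evoked * constants.f(xg)
        noiseless[u] = nl
        if config.noise == "poisson":
            lam = np.maximum(nl, 0.0) / fs
            rate[u] = rng.poisson(lam) * fs
        elif config.noise == "gaussian":
            rate[u] = nl + rng.normal(scale=config.gaussian_sd, size=n_bins)
        else:
            rate[u] = nl.copy()
        units.append(UnitTruth(params=params, s0=s0, psth=psth, effect=eff))

    # analytic MI from the noiseless rates over included presentations
    plag = lag_pupil(pupil, fs=fs)
    pres_inc = [pr for pr in pres if pr["included"]]
    pres_pupil = np.array([plag[pr["bin0"]:pr["bin0"] + nb].mean() for pr in pres_inc])
    pres_active = np.array([pr["active"] for pr in pres_inc])
    med = np.median(pres_pupil)
    pres_large = pres_pupil > med
    for u in range(config.n_units):
        means = np.array([max(noiseless[u, pr["bin0"]:pr["bin0"] + nb].mean(), 0.0)
                          for pr in pres_inc])
        if pres_active.any() and (~pres_active).any():
            units[u].mi_ap = compute_mi(means[pres_active].mean(),
                                        means[~pres_active].mean())
        if pres_large.any() and (~pres_large).any():
            units[u].mi_ls = compute_mi(means[pres_large].mean(),
                                        means[~pres_large].mean())

    rows = [dict(label=blab, start=bs / fs, end=be / fs)
            for blab, bs, be, _ in block_info]
    rows += [dict(label=lab, start=s / fs, end=e / fs) for lab, s, e in epochs]
    ep_df = pd.DataFrame(rows).sort_values(["start", "end"], kind="stable").reset_index(drop=True)

    meta = dict(session_id=f"synth-{seed}", animal="synth", area=config.area,
                unit_ids=[f"u{u:03d}" for u in range(config.n_units)],
                site=f"site-{seed}")
    session = Session(rate=rate, pupil=pupil, epochs=ep_df, meta=meta, fs=fs)
    session.validate()
    truth = GroundTruth(units=units, constants=constants, noiseless_rate=noiseless,
                        p_reg=p_reg, b=active_bin, included_bins=inc_bins, seed=seed)
    return session, truth


def truth_refset(refset, truth: GroundTruth):
    """Swap the estimated PSTH/spontaneous rate for the generator's truth.

    Produces the oracle ReferenceResponseSet used by exact parameter-recovery
    tests: responses stay as observed, but r0/s0 are the generating values.
    """
    from dataclasses import replace as _replace

    stim_ids = [int(s.replace("stim", "")) for s in refset.stims]
    n_units = refset.n_units
    r0 = np.stack([truth.units[u].psth[stim_ids] for u in range(n_units)])
    s0 = np.array([truth.units[u].s0 for u in range(n_units)])
    return _replace(refset, r0=r0, s0=s0)


def generate_population(n_sites: int, seed: int = 0,
                        base_config: GenerativeConfig | None = None,
                        effect_proportions: tuple | None = None) -> list:
    """Generate one session per recording site with distinct seeds.

    Returns a list of (Session, GroundTruth).  Effect-type proportions
    (task, pupil, both, none) apply across units of every site.
    """
    base = base_config or GenerativeConfig()
    if effect_proportions is not None:
        base = replace(base, effect_proportions=tuple(effect_proportions))
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_sites)):
        site_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = replace(base)
        sess, truth = generate_session(cfg, seed=site_seed)
        sess.meta["session_id"] = f"synth-{seed}-site{i:02d}"
        sess.meta["site"] = f"site{i:02d}"
        out.append((sess, truth))
    return out
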