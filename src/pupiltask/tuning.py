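"""Auditory tuning metrics: reverse-correlation STRF, best frequency, response SNR.

The spectro-temporal receptive field (STRF) is estimated by reverse
correlation between the binned spike rate and a (near-white) rippled-noise
spectrogram.  Best frequency (BF) is the center of mass of a spectral tuning
curve taken from the first principal component of the STRF matrix, computed
on the log-frequency axis.  Auditory responsiveness is quantified by a
split-half, Spearman-Brown-corrected reliability of single-trial responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class STRF:
    weights: np.ndarray       # (n_channels, n_lags) gain per unit stimulus power
    freqs: np.ndarray         # (n_channels,) channel center frequencies, Hz
    lags: np.ndarray          # (n_lags,) seconds, >= 0
    bf: float | None = None
    snr: float | None = None


def estimate_strf(stim_spectrogram: np.ndarray, rate: np.ndarray, n_lags: int,
                  freqs: np.ndarray | None = None, fs: float = 20.0) -> STRF:
    """Reverse-correlation STRF: lagged cross-correlation normalized by channel variance.

    weights[f, tau] = sum_t (r(t) - rbar) * (s(f, t - tau) - sbar_f) / (N * var_f).
    Assumes the stimulus is approximately uncorrelated across channels (ripple
    noise or a white fixture); zero-variance channels get zero weights with a
    warning.
    """
    stim = np.asarray(stim_spectrogram, dtype=float)
    r = np.asarray(rate, dtype=float)
    n_ch, n_t = stim.shape
    if r.shape != (n_t,):
        raise ValueError("rate and spectrogram must share a bin grid")
    rd = r - r.mean()
    sd = stim - stim.mean(axis=1, keepdims=True)
    var = stim.var(axis=1)
    w = np.zeros((n_ch, n_lags))
    for tau in range(n_lags):
        if tau == 0:
            w[:, 0] = sd @ rd / n_t
        else:
            w[:, tau] = sd[:, :-tau] @ rd[tau:] / n_t
    zero = var == 0
    if zero.any():
        warnings.warn(f"{zero.sum()} zero-variance channel(s): weights set to 0")
    nz = ~zero
    w[nz] /= var[nz, None]
    w[zero] = 0.0
    if freqs is None:
        freqs = np.logspace(np.log10(500.0), np.log10(16000.0), n_ch)
    return STRF(weights=w, freqs=np.asarray(freqs, dtype=float),
                lags=np.arange(n_lags) / fs)


def best_frequency(strf: STRF) -> float:
    """BF from the rank-1 spectral component of the STRF.

    The first left singular vector is sign-aligned so its maximum-magnitude
    coefficient is positive; BF is the center of mass of its positive part on
    the log-frequency axis, mapped back to Hz.  Invariant to overall STRF
    scaling.
    """
    w = strf.weights
    if not np.any(w):
        raise ValueError("all-zero STRF: BF undefined")
    u, s, vt = np.linalg.svd(w, full_matrices=False)
    spec = u[:, 0]
    if spec[np.argmax(np.abs(spec))] < 0:
        spec = -spec
    pos = np.clip(spec, 0, None)
    if pos.sum() == 0:
        raise ValueError("no positive spectral mass: BF undefined")
    logf = np.log(strf.freqs)
    return float(np.exp(np.sum(pos * logf) / pos.sum()))


def response_snr(per_trial_responses: np.ndarray, n_splits: int = 50,
                 seed: int = 0) -> float:
    """Split-half reliability of single-trial responses, Spearman-Brown corrected.

    Trials are randomly split in half; the two half-PSTHs are correlated and
    the correlation corrected to full length, averaged over splits, floored
    at 0.  Deterministic given ``seed``.
    """
    x = np.asarray(per_trial_responses, dtype=float)
    n_trials = x.shape[0]
    if n_trials < 4:
        raise ValueError("need >= 4 trials for a split-half estimate")
    if np.allclose(x, x.ravel()[0]):
        warnings.warn("constant responses: SNR set to 0")
        return 0.0
    rng = np.random.default_rng(seed)
    vals = []
    half = n_trials // 2
    for _ in range(n_splits):
        perm = rng.permutation(n_trials)
        a = x[perm[:half]].mean(axis=0)
        b = x[perm[half:]].mean(axis=0)
        if a.std() == 0 or b.std() == 0:
            vals.append(0.0)
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        vals.append(2 * r / (1 + r) if r > -1 else -1.0)
    return float(max(np.mean(vals), 0.0))
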