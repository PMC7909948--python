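"""State-dependent encoding model with cross-validated unique-variance attribution.

The full model predicts a unit's single-trial rate from its stimulus PSTH
``r0(t)`` and spontaneous rate ``s0``, re-weighted by two state variables —
normalized pupil size ``p(t)`` and binary task engagement ``b(t)``:

    r_full(t) = s0 * F_d[d0 + dp*p(t) + db*b(t)] + r0(t) * F_g[g0 + gp*p(t) + gb*b(t)]

``F_d``/``F_g`` are fixed saturating nonlinearities (difference of
exponentials, Gompertz form) normalized so F(1) = 1: with all state
coefficients at zero and d0 = g0 = 1, the model reduces exactly to the
state-independent prediction ``s0 + r0(t)``.  Control models shuffle one or
both state regressors in time (per-trial block permutation), and the variance
uniquely explained by each variable is the difference in cross-validated r^2
between the full model and the partial model in which that variable was
shuffled.  Per-unit significance uses a jackknifed t-test over the 20
cross-validation folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import t as t_dist

from .session import ReferenceResponseSet

CATEGORIES = ("task_only", "pupil_only", "both", "ambiguous_state", "none")


@dataclass(frozen=True)
class SigmoidConstants:
    """Fixed shape of the F_d / F_g nonlinearity (not fitted).

    ``mode='gompertz'``: F(x) = B + (1-B) * exp(e - exp(-k*(x - x0))) with
    e = exp(-k*(1 - x0)), a difference-of-exponentials sigmoid that is
    monotone, bounded in [B, B + (1-B)*exp(e)], and passes exactly through
    F(1) = 1 (neutral point).  ``mode='identity'`` is a diagnostic test mode.
    """

    mode: str = "gompertz"
    B: float = 0.0
    k: float = 1.0
    x0: float = field(default=1.0 + float(np.log(np.log(2.0))))

    @classmethod
    def from_amplitude(cls, A: float = 2.0, B: float = 0.0, k: float = 1.0) -> "SigmoidConstants":
        """Solve x0 so that F(1) = 1 for a target saturation amplitude A."""
        if A <= 1 - B:
            raise ValueError("amplitude must exceed 1 - B for F(1)=1 to be reachable")
        x0 = 1.0 + float(np.log(np.log(A / (1.0 - B)))) / k
        return cls(mode="gompertz", B=B, k=k, x0=x0)

    @classmethod
    def identity(cls) -> "SigmoidConstants":
        return cls(mode="identity")

    @property
    def _e(self) -> float:
        # computed with the same expression the forward pass uses at x=1,
        # so F(1) evaluates exp(0.0) == 1.0 exactly
        return np.exp(-self.k * (1.0 - self.x0))

    @property
    def amplitude(self) -> float:
        """Saturation level (x -> +inf)."""
        if self.mode == "identity":
            return np.inf
        return (1.0 - self.B) * float(np.exp(self._e))

    def f(self, x):
        if self.mode == "identity":
            return np.asarray(x, dtype=float) + 0.0
        u = np.exp(-self.k * (x - self.x0))
        return self.B + (1.0 - self.B) * np.exp(self._e - u)

    def df(self, x):
        if self.mode == "identity":
            return np.ones_like(np.asarray(x, dtype=float))
        u = np.exp(-self.k * (x - self.x0))
        return (1.0 - self.B) * np.exp(self._e - u) * self.k * u


DEFAULT_CONSTANTS = SigmoidConstants()


def sigmoid_dexp(x, constants: SigmoidConstants = DEFAULT_CONSTANTS):
    """Difference-of-exponentials sigmoid used for both F_d and F_g."""
    return constants.f(x)


@dataclass
class StateModelParams:
    """The six free coefficients: DC path (d0, dp, db) and gain path (g0, gp, gb)."""

    d0: float = 1.0
    dp: float = 0.0
    db: float = 0.0
    g0: float = 1.0
    gp: float = 0.0
    gb: float = 0.0

    def as_vector(self) -> np.ndarray:
        return np.array([self.d0, self.dp, self.db, self.g0, self.gp, self.gb])

    @classmethod
    def from_vector(cls, v) -> "StateModelParams":
        return cls(*[float(x) for x in v])

    @classmethod
    def neutral(cls) -> "StateModelParams":
        return cls()


@dataclass
class StateSignalSet:
    """State regressors aligned to the included reference presentations.

    ``p`` is the lagged, max-normalized pupil per presentation bin; ``b`` is a
    per-presentation binary regressor (task engagement, or P1/P2 block
    identity for the persistence analysis).
    """

    p: np.ndarray                # (n_pres, nb)
    b: np.ndarray                # (n_pres,)
    trial_ids: np.ndarray        # (n_pres,)
    shuffled_p: bool = False
    shuffled_b: bool = False
    seed: int | None = None


def build_signals(refset: ReferenceResponseSet, b_override: np.ndarray | None = None) -> StateSignalSet:
    b = refset.b if b_override is None else np.asarray(b_override, dtype=float)
    return StateSignalSet(p=refset.p.copy(), b=b.copy(), trial_ids=refset.trial_ids.copy())


def shuffle_state_signal(signal: np.ndarray, trial_ids: np.ndarray, seed: int) -> np.ndarray:
    """Permute per-trial blocks of a signal across trial slots of equal length.

    Values within a trial stay contiguous, preserving within-trial
    autocorrelation; the multiset of per-trial values is preserved.
    """
    signal = np.asarray(signal, dtype=float)
    trial_ids = np.asarray(trial_ids)
    rng = np.random.default_rng(seed)
    # contiguous runs of equal trial id
    change = np.flatnonzero(np.diff(trial_ids) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(trial_ids)]])
    lengths = ends - starts
    out = signal.copy()
    for L in np.unique(lengths):
        idx = np.flatnonzero(lengths == L)
        perm = rng.permutation(len(idx))
        for dst, src in zip(idx, idx[perm]):
            out[starts[dst]:ends[dst]] = signal[starts[src]:ends[src]]
    return out


def _predict(theta: np.ndarray, s0: float, r0: np.ndarray, p: np.ndarray,
             b: np.ndarray, constants: SigmoidConstants) -> np.ndarray:
    d0, dp, db, g0, gp, gb = theta
    xd = d0 + dp * p + db * b
    xg = g0 + gp * p + gb * b
    return s0 * constants.f(xd) + r0 * constants.f(xg)


def evaluate_state_model(params: StateModelParams, refset: ReferenceResponseSet,
                         signals: StateSignalSet, unit: int = 0,
                         constants: SigmoidConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Forward pass of the state model over the included presentation bins.

    Returns the raw (unrectified) predicted rate, flattened over presentations.
    """
    nb = refset.nb
    if signals.p.shape != (refset.n_pres, nb) or len(signals.b) != refset.n_pres:
        raise ValueError("signals are misaligned with the reference presentations")
    r0 = refset.r0[unit][refset.stim_idx].ravel()
    p = signals.p.ravel()
    b = np.repeat(signals.b, nb)
    return _predict(params.as_vector(), float(refset.s0[unit]), r0, p, b, constants)


def _mse_and_grad(theta, s0, r0, p, b, obs, constants):
    d0, dp, db, g0, gp, gb = theta
    xd = d0 + dp * p + db * b
    xg = g0 + gp * p + gb * b
    fd, fg = constants.f(xd), constants.f(xg)
    pred = s0 * fd + r0 * fg
    r = pred - obs
    n = len(obs)
    mse = float(r @ r) / n
    dfd = constants.df(xd) * s0
    dfg = constants.df(xg) * r0
    g = (2.0 / n) * np.array([
        r @ dfd, r @ (dfd * p), r @ (dfd * b),
        r @ dfg, r @ (dfg * p), r @ (dfg * b),
    ])
    return mse, g


@dataclass
class FitResult:
    """Per-fold fits of one model variant with the concatenated held-out prediction."""

    model_spec: str
    params_by_fold: list
    pred: np.ndarray           # (n_pres*nb,) held-out prediction, every bin once
    obs: np.ndarray
    fold_of_pres: np.ndarray   # (n_pres,)
    pred_by_fold: list         # list of held-out prediction arrays per fold
    obs_by_fold: list
    converged: np.ndarray      # (n_folds,) bool
    signals: StateSignalSet | None = None


def subset_presentations(refset: ReferenceResponseSet, mask: np.ndarray) -> ReferenceResponseSet:
    """Restrict a ReferenceResponseSet to presentations where ``mask`` is True."""
    mask = np.asarray(mask, dtype=bool)
    keep_trials = np.unique(refset.trial_ids[mask])
    sil_keep = np.isin(refset.silence_trials, keep_trials)
    return replace(
        refset,
        resp=refset.resp[:, mask, :],
        p=refset.p[mask],
        b=refset.b[mask],
        trial_ids=refset.trial_ids[mask],
        stim_idx=refset.stim_idx[mask],
        block_ord=refset.block_ord[mask],
        mean_pupil=refset.mean_pupil[mask],
        silence_sum=refset.silence_sum[:, sil_keep],
        silence_count=refset.silence_count[sil_keep],
        silence_trials=refset.silence_trials[sil_keep],
    )


def resample_presentations(refset: ReferenceResponseSet, idx: np.ndarray,
                           recompute_r0: bool = True) -> ReferenceResponseSet:
    """Rebuild a ReferenceResponseSet from a presentation index vector.

    Used for bootstrap resampling; with ``recompute_r0`` the PSTH is
    re-estimated from the resampled presentations (spontaneous-rate windows
    are kept as is).
    """
    idx = np.asarray(idx)
    out = replace(
        refset,
        resp=refset.resp[:, idx, :],
        p=refset.p[idx],
        b=refset.b[idx],
        trial_ids=refset.trial_ids[idx],
        stim_idx=refset.stim_idx[idx],
        block_ord=refset.block_ord[idx],
        mean_pupil=refset.mean_pupil[idx],
    )
    if recompute_r0:
        r0 = refset.r0.copy()
        for s in range(r0.shape[1]):
            m = out.stim_idx == s
            if m.any():
                r0[:, s, :] = out.resp[:, m, :].mean(axis=1) - out.s0[:, None]
        out = replace(out, r0=r0)
    return out


MODEL_SPECS = ("full", "null", "task_only", "pupil_only")
_BOUNDS = [(-5.0, 5.0)] * 6
_OPT_OPTIONS = {"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9}


def fit_full_data(refset: ReferenceResponseSet, unit: int = 0,
                  constants: SigmoidConstants = DEFAULT_CONSTANTS,
                  b_override: np.ndarray | None = None,
                  reestimate_r0: bool = False) -> StateModelParams:
    """Single full-model fit on all included presentations (no cross-validation).

    Used for parameter-recovery diagnostics where a point estimate and
    bootstrap standard errors are wanted rather than held-out predictions.
    """
    nb = refset.nb
    obs = refset.resp[unit].ravel()
    p = refset.p.ravel()
    b_pres = refset.b if b_override is None else np.asarray(b_override, dtype=float)
    b = np.repeat(b_pres, nb)
    r0 = refset.r0[unit][refset.stim_idx].ravel()
    s0 = float(refset.s0[unit])
    res = minimize(_mse_and_grad, StateModelParams.neutral().as_vector(),
                   args=(s0, r0, p, b, obs, constants), jac=True,
                   method="L-BFGS-B", bounds=_BOUNDS, options=_OPT_OPTIONS)
    return StateModelParams.from_vector(res.x)


def bootstrap_recovery(refset: ReferenceResponseSet, unit: int = 0,
                       n_boot: int = 30, seed: int = 0,
                       constants: SigmoidConstants = DEFAULT_CONSTANTS
                       ) -> tuple[StateModelParams, np.ndarray]:
    """Full-model point estimate plus bootstrap SEs of the six coefficients.

    Included presentations are resampled with replacement; the PSTH is
    re-estimated on each resample so the SEs include PSTH-estimation noise.
    """
    est = fit_full_data(refset, unit=unit, constants=constants)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 6))
    for i in range(n_boot):
        idx = rng.integers(0, refset.n_pres, refset.n_pres)
        rs = resample_presentations(refset, idx, recompute_r0=True)
        boots[i] = fit_full_data(rs, unit=unit, constants=constants).as_vector()
    return est, boots.std(axis=0, ddof=1)


def fit_state_model(refset: ReferenceResponseSet, unit: int = 0, model_spec: str = "full",
                    n_folds: int = 20, seed: int = 0,
                    constants: SigmoidConstants = DEFAULT_CONSTANTS,
                    b_override: np.ndarray | None = None,
                    n_restarts: int = 3, reestimate_r0: bool = True) -> FitResult:
    """Fit one model variant with trial-interleaved k-fold cross-validation.

    ``model_spec`` selects which regressors are shuffled in time before
    fitting: 'full' (none), 'task_only' (pupil shuffled), 'pupil_only' (task
    shuffled), 'null' (both shuffled).  The same shuffle permutations (derived
    from ``seed``) are reused across model variants of one unit so partial
    models differ only in which alignment is destroyed.  Within each fold the
    PSTH r0 and spontaneous rate s0 are re-estimated from the training trials
    only, the six coefficients minimize training MSE (bounded quasi-Newton
    from the neutral point, with random restarts on non-convergence), and the
    held-out bins are predicted; the concatenated prediction covers every
    included bin exactly once.
    """
    if model_spec not in MODEL_SPECS:
        raise ValueError(f"unknown model_spec {model_spec!r}")
    nb = refset.nb
    n_pres = refset.n_pres
    obs2d = refset.resp[unit]
    obs = obs2d.ravel()
    p_flat = refset.p.ravel()
    b_pres = refset.b if b_override is None else np.asarray(b_override, dtype=float)
    b_flat = np.repeat(b_pres, nb)
    tid_flat = np.repeat(refset.trial_ids, nb)

    shuf_p = model_spec in ("task_only", "null")
    shuf_b = model_spec in ("pupil_only", "null")
    if shuf_p:
        p_flat = shuffle_state_signal(p_flat, tid_flat, seed=2 * seed + 1)
    if shuf_b:
        b_flat = shuffle_state_signal(b_flat, tid_flat, seed=2 * seed + 2)
    signals = StateSignalSet(p=p_flat.reshape(n_pres, nb), b=b_pres,
                             trial_ids=refset.trial_ids, shuffled_p=shuf_p,
                             shuffled_b=shuf_b, seed=seed)

    # trial-interleaved fold assignment
    trials, first = np.unique(refset.trial_ids, return_index=True)
    trials = trials[np.argsort(first)]
    fold_of_trial = {t: i % n_folds for i, t in enumerate(trials)}
    fold_of_pres = np.array([fold_of_trial[t] for t in refset.trial_ids])

    rng = np.random.default_rng(seed)
    pred = np.full(n_pres * nb, np.nan)
    params_by_fold, pred_by_fold, obs_by_fold = [], [], []
    converged = np.ones(n_folds, dtype=bool)
    x_init = StateModelParams.neutral().as_vector()

    for f in range(n_folds):
        test = fold_of_pres == f
        train = ~test
        if not test.any():
            params_by_fold.append(None)
            pred_by_fold.append(np.array([]))
            obs_by_fold.append(np.array([]))
            continue
        if reestimate_r0:
            train_trials = np.unique(refset.trial_ids[train])
            sil = np.isin(refset.silence_trials, train_trials)
            tot = refset.silence_count[sil].sum()
            s0_f = float(refset.silence_sum[unit, sil].sum() / tot) if tot > 0 else float(refset.s0[unit])
            r0_f = np.empty((refset.r0.shape[1], nb))
            for s in range(refset.r0.shape[1]):
                m = train & (refset.stim_idx == s)
                if m.any():
                    r0_f[s] = obs2d[m].mean(axis=0) - s0_f
                else:
                    r0_f[s] = refset.r0[unit, s]
        else:
            s0_f = float(refset.s0[unit])
            r0_f = refset.r0[unit]
        r0_flat = r0_f[refset.stim_idx].ravel()

        bins_train = np.repeat(train, nb)
        bins_test = np.repeat(test, nb)
        args = (s0_f, r0_flat[bins_train], p_flat[bins_train], b_flat[bins_train],
                obs[bins_train], constants)
        best = minimize(_mse_and_grad, x_init, args=args, jac=True,
                        method="L-BFGS-B", bounds=_BOUNDS,
                        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
        tries = 0
        while not best.success and tries < n_restarts:
            x_r = x_init + rng.normal(scale=0.5, size=6)
            res = minimize(_mse_and_grad, x_r, args=args, jac=True,
                           method="L-BFGS-B", bounds=_BOUNDS,
                           options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
            if res.fun < best.fun or (res.success and not best.success):
                best = res
            tries += 1
        if not best.success:
            converged[f] = False
            warnings.warn(f"fold {f} ({model_spec}): optimizer did not converge; flagged")
        theta = best.x
        params_by_fold.append(StateModelParams.from_vector(theta))
        pr = _predict(theta, s0_f, r0_flat[bins_test], p_flat[bins_test],
                      b_flat[bins_test], constants)
        pred[bins_test] = pr
        pred_by_fold.append(pr)
        obs_by_fold.append(obs[bins_test])

    assert not np.isnan(pred).any(), "cross-validation failed to cover every bin"
    return FitResult(model_spec=model_spec, params_by_fold=params_by_fold, pred=pred,
                     obs=obs, fold_of_pres=fold_of_pres, pred_by_fold=pred_by_fold,
                     obs_by_fold=obs_by_fold, converged=converged, signals=signals)


def compute_r2(pred: np.ndarray, obs: np.ndarray) -> float:
    """Squared Pearson correlation; 0 by convention when either series is constant."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("pred and obs must share a length >= 2")
    sp, so = pred.std(), obs.std()
    if sp == 0 or so == 0:
        return 0.0
    r = float(np.corrcoef(pred, obs)[0, 1])
    return r * r


def jackknife_significance(pred_by_fold_a: list, pred_by_fold_b: list,
                           obs_by_fold: list) -> float:
    """Two-sided p for a difference in prediction correlation, jackknifed over folds.

    Leave-one-fold-out estimates of r(A, obs) - r(B, obs) feed a t statistic
    with (n-1)-inflated jackknife standard error and n-1 degrees of freedom.
    """
    usable = [i for i, o in enumerate(obs_by_fold) if len(o) > 0]
    n = len(usable)
    if n < 3:
        return float("nan")

    def _corr(x, y):
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    d = np.empty(n)
    for j, fj in enumerate(usable):
        keep = [f for f in usable if f != fj]
        a = np.concatenate([pred_by_fold_a[f] for f in keep])
        bb = np.concatenate([pred_by_fold_b[f] for f in keep])
        o = np.concatenate([obs_by_fold[f] for f in keep])
        d[j] = _corr(a, o) - _corr(bb, o)
    mean_d = d.mean()
    se = np.sqrt((n - 1) / n * np.sum((d - mean_d) ** 2))
    if se == 0:
        return 1.0 if mean_d == 0 else 0.0
    t = mean_d / se
    return float(2 * t_dist.sf(abs(t), df=n - 1))


@dataclass
class ModelEvaluation:
    """Cross-validated performance and attribution summary for one unit."""

    r2_full: float
    r2_null: float
    r2_task_only: float
    r2_pupil_only: float
    r2_task_unique: float
    r2_pupil_unique: float
    p_state: float
    p_task_unique: float
    p_pupil_unique: float
    category: str
    fits: dict = field(default_factory=dict, repr=False)


def unique_variance(ev: ModelEvaluation) -> tuple[float, float]:
    """(task_unique, pupil_unique) = r2_full minus the respective partial-model r2.

    Slightly negative values are preserved: they are evidence of overfitting
    noise and feed the jackknife test.
    """
    return ev.r2_full - ev.r2_pupil_only, ev.r2_full - ev.r2_task_only


def classify_unit(p_state: float, p_task_unique: float, p_pupil_unique: float,
                  alpha: float = 0.05) -> str:
    """Assign the four-way state-modulation category (or 'none')."""
    if not (p_state < alpha):
        return "none"
    sig_t = p_task_unique < alpha
    sig_p = p_pupil_unique < alpha
    if sig_t and sig_p:
        return "both"
    if sig_t:
        return "task_only"
    if sig_p:
        return "pupil_only"
    return "ambiguous_state"


def evaluate_unit(refset: ReferenceResponseSet, unit: int = 0, seed: int = 0,
                  n_folds: int = 20, alpha: float = 0.05,
                  constants: SigmoidConstants = DEFAULT_CONSTANTS,
                  b_override: np.ndarray | None = None) -> ModelEvaluation:
    """Fit all four model variants for one unit and summarize attribution."""
    fits = {
        spec: fit_state_model(refset, unit=unit, model_spec=spec, n_folds=n_folds,
                              seed=seed, constants=constants, b_override=b_override)
        for spec in MODEL_SPECS
    }
    obs = fits["full"].obs
    r2 = {spec: compute_r2(fits[spec].pred, obs) for spec in MODEL_SPECS}
    p_state = jackknife_significance(fits["full"].pred_by_fold,
                                     fits["null"].pred_by_fold,
                                     fits["full"].obs_by_fold)
    p_task = jackknife_significance(fits["full"].pred_by_fold,
                                    fits["pupil_only"].pred_by_fold,
                                    fits["full"].obs_by_fold)
    p_pupil = jackknife_significance(fits["full"].pred_by_fold,
                                     fits["task_only"].pred_by_fold,
                                     fits["full"].obs_by_fold)
    ev = ModelEvaluation(
        r2_full=r2["full"], r2_null=r2["null"], r2_task_only=r2["task_only"],
        r2_pupil_only=r2["pupil_only"],
        r2_task_unique=r2["full"] - r2["pupil_only"],
        r2_pupil_unique=r2["full"] - r2["task_only"],
        p_state=p_state, p_task_unique=p_task, p_pupil_unique=p_pupil,
        category=classify_unit(p_state, p_task, p_pupil, alpha=alpha),
        fits=fits,
    )
    return ev
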