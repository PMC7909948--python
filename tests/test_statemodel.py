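"""State-dependent GLM: nonlinearity, shuffles, CV fitting, attribution."""

import numpy as np
import pytest

import pupiltask as pt
from pupiltask.simulate import truth_refset
from pupiltask.statemodel import (
    DEFAULT_CONSTANTS,
    fit_state_model,
    resample_presentations,
    subset_presentations,
)


def test_sigmoid_passes_through_one_exactly():
    c = DEFAULT_CONSTANTS
    assert c.f(1.0) == 1.0                      # bitwise, by construction
    assert pt.sigmoid_dexp(np.array([1.0]))[0] == 1.0
    assert c.amplitude == 2.0                   # default saturation level


def test_sigmoid_monotone_and_bounded():
    c = DEFAULT_CONSTANTS
    x = np.linspace(-10, 10, 2001)
    y = c.f(x)
    assert (np.diff(y) >= 0).all()                  # flat only where exp underflows
    xm = np.linspace(-3, 5, 801)
    assert (np.diff(c.f(xm)) > 0).all()             # strictly increasing when representable
    assert y.min() >= c.B and y.max() <= c.amplitude
    c2 = pt.SigmoidConstants.from_amplitude(A=3.0, B=0.1, k=2.0)
    assert c2.f(1.0) == pytest.approx(1.0, abs=1e-15)
    assert c2.amplitude == pytest.approx(3.0, rel=1e-12)
    with pytest.raises(ValueError):
        pt.SigmoidConstants.from_amplitude(A=0.5, B=0.0)


def test_sigmoid_gradient_matches_finite_differences():
    c = DEFAULT_CONSTANTS
    x = np.linspace(-3, 4, 29)
    h = 1e-6
    num = (c.f(x + h) - c.f(x - h)) / (2 * h)
    assert np.allclose(c.df(x), num, atol=1e-6)
    ident = pt.SigmoidConstants.identity()
    assert np.array_equal(ident.f(x), x)
    assert np.array_equal(ident.df(x), np.ones_like(x))


def test_neutral_params_equal_null_prediction_bitwise(small_refset):
    sig = pt.build_signals(small_refset)
    for unit in range(small_refset.n_units):
        pred = pt.evaluate_state_model(pt.StateModelParams.neutral(),
                                       small_refset, sig, unit=unit)
        null = small_refset.s0[unit] + small_refset.r0[unit][small_refset.stim_idx].ravel()
        assert np.array_equal(pred, null)


def test_shuffle_preserves_trial_blocks():
    rng = np.random.default_rng(0)
    trial_ids = np.repeat([3, 7, 9, 12, 15], [15, 30, 15, 30, 15])
    x = rng.normal(size=len(trial_ids))
    y = pt.shuffle_state_signal(x, trial_ids, seed=5)
    assert not np.array_equal(x, y)
    assert np.array_equal(y, pt.shuffle_state_signal(x, trial_ids, seed=5))
    assert not np.array_equal(y, pt.shuffle_state_signal(x, trial_ids, seed=6))
    # per-trial blocks move as units, only between equal-length slots
    def blocks(sig):
        out = {}
        for t in np.unique(trial_ids):
            out[t] = sig[trial_ids == t]
        return out
    bx, by = blocks(x), blocks(y)
    for t, blk in by.items():
        matches = [s for s, b in bx.items() if len(b) == len(blk) and np.array_equal(b, blk)]
        assert matches, "shuffled block is not one of the original equal-length blocks"


def test_compute_r2_oracle():
    assert pt.compute_r2(np.array([1.0, 2, 3, 4]), np.array([1.0, 1, 3, 3])) == \
        pytest.approx(0.800, abs=1e-12)
    assert pt.compute_r2(np.ones(5), np.arange(5.0)) == 0.0
    with pytest.raises(ValueError):
        pt.compute_r2(np.ones(3), np.ones(4))


def test_unique_variance_is_exact_subtraction():
    ev = pt.ModelEvaluation(r2_full=0.30, r2_null=0.05, r2_task_only=0.28,
                            r2_pupil_only=0.21, r2_task_unique=0.0,
                            r2_pupil_unique=0.0, p_state=0.0, p_task_unique=0.0,
                            p_pupil_unique=0.0, category="both")
    tu, pu = pt.unique_variance(ev)
    assert tu == ev.r2_full - ev.r2_pupil_only
    assert pu == ev.r2_full - ev.r2_task_only
    assert tu == pytest.approx(0.09, abs=1e-12)


def test_classify_unit_decision_table():
    a = 0.05
    assert pt.classify_unit(0.5, 0.01, 0.01, a) == "none"      # state gate first
    assert pt.classify_unit(0.01, 0.01, 0.5, a) == "task_only"
    assert pt.classify_unit(0.01, 0.5, 0.01, a) == "pupil_only"
    assert pt.classify_unit(0.01, 0.01, 0.01, a) == "both"
    assert pt.classify_unit(0.01, 0.5, 0.5, a) == "ambiguous_state"
    assert pt.classify_unit(0.05, 0.01, 0.01, a) == "none"     # boundary not significant


def test_jackknife_edge_cases():
    rng = np.random.default_rng(1)
    obs = [rng.normal(size=50) for _ in range(10)]
    same = [o * 0.5 for o in obs]
    assert pt.jackknife_significance(same, [s.copy() for s in same], obs) == 1.0
    noise = [rng.normal(size=50) for _ in range(10)]
    p = pt.jackknife_significance(same, noise, obs)
    assert p < 1e-6      # perfect vs unrelated prediction
    assert np.isnan(pt.jackknife_significance(same[:2], noise[:2], obs[:2]))


def test_cv_folds_interleave_trials_and_cover_all_bins(small_refset):
    fit = fit_state_model(small_refset, unit=0, model_spec="full", seed=0)
    assert not np.isnan(fit.pred).any()
    assert len(fit.pred) == small_refset.n_pres * small_refset.nb
    # trial-interleaved assignment: consecutive trials land in consecutive folds
    trials, first = np.unique(small_refset.trial_ids, return_index=True)
    trials = trials[np.argsort(first)]
    for i, t in enumerate(trials):
        assert (fit.fold_of_pres[small_refset.trial_ids == t] == i % 20).all()
    # no trial is split across folds
    for t in trials:
        assert len(np.unique(fit.fold_of_pres[small_refset.trial_ids == t])) == 1


def test_partial_models_share_shuffles(small_refset):
    f_task = fit_state_model(small_refset, unit=0, model_spec="task_only", seed=3)
    f_null = fit_state_model(small_refset, unit=0, model_spec="null", seed=3)
    f_pupil = fit_state_model(small_refset, unit=0, model_spec="pupil_only", seed=3)
    assert np.array_equal(f_task.signals.p, f_null.signals.p)   # same pupil shuffle
    assert f_task.signals.shuffled_p and not f_task.signals.shuffled_b
    assert f_pupil.signals.shuffled_b and not f_pupil.signals.shuffled_p
    full = fit_state_model(small_refset, unit=0, model_spec="full", seed=3)
    assert np.array_equal(full.signals.p.ravel(), small_refset.p.ravel())


def test_noiseless_identity_recovery_is_exact():
    """With no noise, identity nonlinearity and the true PSTH, the fit recovers
    the generating coefficients to optimizer precision in every fold."""
    ident = pt.SigmoidConstants.identity()
    cfg = pt.GenerativeConfig(trials_per_block=10, n_units=1, noise="none",
                              constants=ident, unit_effects=("both",))
    session, truth = pt.generate_session(cfg, seed=3)
    rs = truth_refset(pt.extract_reference_responses(session), truth)
    fit = fit_state_model(rs, unit=0, model_spec="full", seed=0,
                          constants=ident, reestimate_r0=False)
    tv = truth.units[0].params.as_vector()
    for params in fit.params_by_fold:
        assert np.abs(params.as_vector() - tv).max() < 1e-3
    assert pt.compute_r2(fit.pred, fit.obs) > 0.999999


def test_evaluate_unit_summary(small_refset):
    ev = pt.evaluate_unit(small_refset, unit=0, seed=11)
    assert set(ev.fits) == {"full", "null", "task_only", "pupil_only"}
    assert ev.r2_task_unique == ev.r2_full - ev.r2_pupil_only
    assert ev.r2_pupil_unique == ev.r2_full - ev.r2_task_only
    assert ev.category in ("task_only", "pupil_only", "both", "ambiguous_state", "none")
    assert 0 <= ev.r2_full <= 1 and 0 <= ev.r2_null <= 1
    # unit 0 was generated with real state modulation; unit 1 without
    assert ev.r2_full > 0


def test_subset_and_resample_presentations(small_refset):
    mask = small_refset.b == 0
    sub = subset_presentations(small_refset, mask)
    assert sub.n_pres == mask.sum()
    assert (sub.b == 0).all()
    assert np.array_equal(sub.resp[:, 0, :], small_refset.resp[:, np.flatnonzero(mask)[0], :])
    idx = np.arange(small_refset.n_pres)[::-1]
    rev = resample_presentations(small_refset, idx, recompute_r0=True)
    assert rev.n_pres == small_refset.n_pres
    # PSTH recomputed from the same multiset of presentations is unchanged
    assert np.allclose(rev.r0, small_refset.r0)


def test_unknown_model_spec_raises(small_refset):
    with pytest.raises(ValueError):
        fit_state_model(small_refset, model_spec="bogus")
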