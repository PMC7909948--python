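"""Synthetic-session generator: invariants, determinism, ground-truth oracles."""

import numpy as np
import pytest
from scipy.stats import binom

import pupiltask as pt
from pupiltask.session import bin_slice
from pupiltask.simulate import truth_refset


def test_same_seed_is_identical():
    cfg = pt.GenerativeConfig(trials_per_block=8, n_units=2)
    s1, t1 = pt.generate_session(cfg, seed=9)
    s2, t2 = pt.generate_session(cfg, seed=9)
    assert np.array_equal(s1.rate, s2.rate)
    assert np.array_equal(s1.pupil, s2.pupil)
    assert s1.epochs.equals(s2.epochs)
    for u1, u2 in zip(t1.units, t2.units):
        assert np.array_equal(u1.params.as_vector(), u2.params.as_vector())
    s3, _ = pt.generate_session(cfg, seed=10)
    assert not np.array_equal(s1.rate, s3.rate)


def test_generated_sessions_validate_and_sit_on_grid(small_session):
    session, _ = small_session
    session.validate()   # structural invariants hold
    fs = session.fs
    t = session.epochs[["start", "end"]].to_numpy()
    assert np.allclose(t * fs, np.round(t * fs), atol=1e-9)
    # references are exactly 15 bins with 0.7 s gaps inside a trial
    refs = session.epochs[session.epochs["label"].str.startswith("REFERENCE:")]
    for _, r in refs.iterrows():
        sl = bin_slice(r["start"], r["end"], fs)
        assert sl.stop - sl.start == 15


def test_flat_hazard_trial_lengths():
    cfg = pt.GenerativeConfig(blocks=("passive",), trials_per_block=600,
                              n_units=1, unit_effects=("none",))
    session, _ = pt.generate_session(cfg, seed=17)
    refs = session.epochs[session.epochs["label"].str.startswith("REFERENCE:")]
    trials = session.epochs[session.epochs["label"].str.startswith("TRIAL:")]
    counts = []
    for _, tr in trials.iterrows():
        m = (refs["start"] >= tr["start"] - 1e-9) & (refs["end"] <= tr["end"] + 1e-9)
        counts.append(int(m.sum()))
    counts = np.array(counts)
    assert counts.min() >= 2 and counts.max() <= 5
    # flat hazard 1/3: P(n) = (2/3)^(n-2)/3 for n=2..4, remainder at 5
    n = len(counts)
    probs = {2: 1 / 3, 3: 2 / 9, 4: 4 / 27, 5: 8 / 27}
    for k, pk in probs.items():
        lo, hi = binom.interval(0.999, n, pk)
        assert lo <= (counts == k).sum() <= hi, f"hazard violated at n_refs={k}"


def test_pupil_block_dependence_and_positivity(small_session):
    session, truth = small_session
    assert (session.pupil > 0).all()
    active = truth.b == 1
    assert session.pupil[active].mean() > session.pupil[~active].mean()


def test_pupil_engagement_correlation_monotone_in_shift():
    cors = []
    for shift in (2.0, 8.0, 15.0):
        cfg = pt.GenerativeConfig(trials_per_block=10, n_units=1,
                                  unit_effects=("none",), pupil_active_shift=shift)
        session, truth = pt.generate_session(cfg, seed=23)
        cors.append(np.corrcoef(session.pupil, truth.b)[0, 1])
    assert cors[0] < cors[1] < cors[2]


def test_quiet_pupil_is_piecewise_constant():
    cfg = pt.GenerativeConfig(trials_per_block=4, n_units=1, unit_effects=("none",),
                              pupil_ou_sigma=0.0, dilation_amp_active=0.0,
                              dilation_amp_passive=0.0)
    session, truth = pt.generate_session(cfg, seed=2)
    expect = cfg.pupil_passive_baseline + cfg.pupil_active_shift * truth.b
    assert np.array_equal(session.pupil, expect)


def test_no_noise_rate_equals_model_bitwise():
    cfg = pt.GenerativeConfig(trials_per_block=5, n_units=2, noise="none")
    session, truth = pt.generate_session(cfg, seed=4)
    assert np.array_equal(session.rate, truth.noiseless_rate)
    # and the forward model with the stored truth reproduces the included bins
    rs = truth_refset(pt.extract_reference_responses(session), truth)
    sig = pt.build_signals(rs)
    for u in range(2):
        pred = pt.evaluate_state_model(truth.units[u].params, rs, sig, unit=u,
                                       constants=truth.constants)
        assert np.array_equal(pred, rs.resp[u].ravel())


def test_generator_offsets_make_truth_psth_neutral():
    """d0/g0 are set so the mean state terms over included bins equal one."""
    cfg = pt.GenerativeConfig(trials_per_block=8, n_units=3)
    _, truth = pt.generate_session(cfg, seed=6)
    p_bar = truth.p_reg[truth.included_bins].mean()
    b_bar = truth.b[truth.included_bins].mean()
    for u in truth.units:
        th = u.params
        assert th.d0 + th.dp * p_bar + th.db * b_bar == pytest.approx(1.0, abs=1e-12)
        assert th.g0 + th.gp * p_bar + th.gb * b_bar == pytest.approx(1.0, abs=1e-12)


def test_analytic_mi_matches_noiseless_rates(small_session):
    """Stored MI truth equals MI recomputed from the noiseless rates (exact)."""
    session, truth = small_session
    rs = pt.extract_reference_responses(session)
    for u, ut in enumerate(truth.units):
        means = []
        for i in range(rs.n_pres):
            b0 = int(rs.table[rs.table["included"]].iloc[i]["bin0"])
            means.append(max(truth.noiseless_rate[u, b0:b0 + rs.nb].mean(), 0.0))
        means = np.array(means)
        active = rs.b == 1
        assert pt.compute_mi(means[active].mean(), means[~active].mean()) == ut.mi_ap


def test_poisson_noise_statistics():
    cfg = pt.GenerativeConfig(trials_per_block=20, n_units=1, unit_effects=("none",))
    session, truth = pt.generate_session(cfg, seed=8)
    lam = truth.noiseless_rate[0] / cfg.fs        # expected counts per bin
    counts = session.rate[0] / cfg.fs
    assert np.allclose(counts, np.round(counts))  # integer counts scaled by fs
    # mean matches within 4 sigma of the summed Poisson variability
    tot, var = counts.sum(), lam.sum()
    assert abs(tot - var) < 4 * np.sqrt(var)


def test_effect_proportions_and_population():
    pops = pt.generate_population(3, seed=31,
                                  base_config=pt.GenerativeConfig(
                                      trials_per_block=4, n_units=3, noise="none"),
                                  effect_proportions=(0.0, 0.0, 0.0, 1.0))
    assert len(pops) == 3
    sites = set()
    for sess, truth in pops:
        sites.add(sess.meta["site"])
        assert all(u.effect == "none" for u in truth.units)
        for u in truth.units:
            assert np.array_equal(u.params.as_vector(), [1, 0, 0, 1, 0, 0])
    assert len(sites) == 3
    # same master seed -> identical population
    pops2 = pt.generate_population(3, seed=31,
                                   base_config=pt.GenerativeConfig(
                                       trials_per_block=4, n_units=3, noise="none"),
                                   effect_proportions=(0.0, 0.0, 0.0, 1.0))
    assert np.array_equal(pops[1][0].rate, pops2[1][0].rate)


def test_config_validation():
    with pytest.raises(ValueError):
        pt.GenerativeConfig(ref_dur=0.73).validate()
    with pytest.raises(ValueError):
        pt.GenerativeConfig(noise="laplace").validate()
    with pytest.raises(ValueError):
        pt.GenerativeConfig(coef_sign="negative").validate()
    with pytest.raises(ValueError):
        pt.generate_session(pt.GenerativeConfig(n_units=2, unit_effects=("task",)))
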