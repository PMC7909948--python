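"""Session container, epoch parsing, extraction and preprocessing."""

import numpy as np
import pandas as pd
import pytest

import pupiltask as pt
from pupiltask.session import PUPIL_LAG, bin_slice

from conftest import build_toy_session


def test_bin_slice_half_open_convention():
    # [1.0, 1.75) at 20 Hz -> bins 20..34 (15 bins); left edge owns the bin
    sl = bin_slice(1.0, 1.75)
    assert (sl.start, sl.stop) == (20, 35)
    assert sl.stop - sl.start == 15
    # boundary bin at 1.75 s belongs to the next interval
    assert bin_slice(1.75, 2.45).start == 35
    # float-noise robustness around the grid
    assert bin_slice(1.0 - 1e-12, 1.75 + 1e-12) == sl


def test_lag_pupil_holds_first_value():
    x = np.arange(10, dtype=float)
    y = pt.lag_pupil(x, lag=0.15, fs=20.0)  # 3 bins
    assert np.array_equal(y[:3], [0.0, 0.0, 0.0])
    assert np.array_equal(y[3:], x[:-3])
    assert np.array_equal(pt.lag_pupil(x, lag=0.0), x)
    with pytest.raises(ValueError):
        pt.lag_pupil(x, lag=0.13)  # not on the bin grid
    with pytest.raises(ValueError):
        pt.lag_pupil(x, lag=-0.05)


def test_session_roundtrip_is_identical(tmp_path, small_session):
    session, _ = small_session
    d1, d2 = tmp_path / "a", tmp_path / "b"
    pt.save_session(session, d1)
    loaded = pt.load_session(d1)
    assert np.array_equal(loaded.rate, session.rate)
    assert np.array_equal(loaded.pupil, session.pupil)
    assert loaded.fs == session.fs
    assert loaded.meta == session.meta
    # epoch times round-trip bitwise through the %.6f text format
    assert np.array_equal(loaded.epochs["start"].to_numpy(),
                          session.epochs["start"].to_numpy())
    assert np.array_equal(loaded.epochs["end"].to_numpy(),
                          session.epochs["end"].to_numpy())
    # save(load(save(x))) is byte-identical to save(x)
    pt.save_session(loaded, d2)
    for name in ("signals.h5", "epochs.csv", "meta.json"):
        if name.endswith(".h5"):
            continue  # h5 containers embed allocation metadata; arrays compared above
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_load_missing_pieces_raises(tmp_path, small_session):
    session, _ = small_session
    pt.save_session(session, tmp_path / "s")
    (tmp_path / "s" / "epochs.csv").unlink()
    with pytest.raises(pt.SessionFormatError):
        pt.load_session(tmp_path / "s")
    with pytest.raises(pt.SessionFormatError):
        pt.load_session(tmp_path / "nope")


def test_validate_rejects_bad_structure(toy_session):
    bad = pt.Session(rate=toy_session.rate, pupil=toy_session.pupil[:-1],
                     epochs=toy_session.epochs, meta=toy_session.meta)
    with pytest.raises(pt.SessionValidationError):
        bad.validate()
    ep = toy_session.epochs.copy()
    ep.loc[len(ep)] = ["HIT", 1.0, 4.65]  # second outcome on trial 0
    bad2 = pt.Session(rate=toy_session.rate, pupil=toy_session.pupil,
                      epochs=ep, meta=toy_session.meta)
    with pytest.raises(pt.SessionValidationError):
        bad2.validate()
    ep2 = toy_session.epochs.copy()
    ep2.loc[ep2["label"] == "PASSIVE_BLOCK:1", "end"] = 6.0  # blocks no longer tile
    bad3 = pt.Session(rate=toy_session.rate, pupil=toy_session.pupil,
                      epochs=ep2, meta=toy_session.meta)
    with pytest.raises(pt.SessionValidationError):
        bad3.validate()


def test_extraction_on_toy_session(toy_session):
    rs = pt.extract_reference_responses(toy_session)
    assert rs.n_pres == 3
    assert rs.stims == ["stimA", "stimB"]
    assert rs.nb == 15
    assert np.array_equal(rs.b, [0.0, 0.0, 0.0])
    assert np.array_equal(rs.trial_ids, [0, 0, 1])
    # responses are the raw rate at the reference bins
    assert np.array_equal(rs.resp[0, 0], toy_session.rate[0, 20:35])
    assert np.array_equal(rs.resp[0, 2], toy_session.rate[0, 140:155])
    # PSTH + s0 reconstructs the included mean exactly
    mean_a = (rs.resp[0, 0] + rs.resp[0, 2]) / 2
    assert np.allclose(rs.r0[0, 0] + rs.s0[0], mean_a)
    # pupil regressor is the lagged trace over the session maximum
    plag = pt.lag_pupil(toy_session.pupil, lag=PUPIL_LAG)
    assert np.array_equal(rs.p[0], plag[20:35] / toy_session.pupil.max())


def test_exclusion_reasons():
    session = build_toy_session()
    ep = session.epochs.copy()
    # make trial 1 an active FA with a lick during the reference
    ep.loc[ep["label"] == "PASSIVE_BLOCK:1", "end"] = 5.0
    ep.loc[len(ep)] = ["ACTIVE_BLOCK:1", 5.0, 12.0]
    ep.loc[ep["label"] == "CR", "label"] = ["CR", "FA"]
    bad = pt.Session(rate=session.rate, pupil=session.pupil, epochs=ep,
                     meta=session.meta)
    bad.validate()
    rs = pt.extract_reference_responses(bad)
    tab = rs.table
    assert rs.n_pres == 2  # trial 1's presentation excluded
    row = tab[tab["trial"] == 1].iloc[0]
    assert not row["included"] and row["reason"] == "active_nonhit"


def test_target_overlap_and_truncation_excluded():
    session = build_toy_session()
    ep = session.epochs.copy()
    # move trial 0's target onto the second reference
    ep.loc[(ep["label"] == "TARGET") & (ep["start"] == 3.9), ["start", "end"]] = [3.0, 3.75]
    sess = pt.Session(rate=session.rate, pupil=session.pupil, epochs=ep,
                      meta=session.meta)
    rs = pt.extract_reference_responses(sess)
    tab = rs.table
    assert (tab.loc[tab["stim"] == "stimB", "reason"] == "target_overlap").all()
    # a reference whose bins run past the end of the recording is truncated
    rows = pd.DataFrame(
        [("PASSIVE_BLOCK:1", 0.0, 7.4),
         ("TRIAL:0", 1.0, 4.65),
         ("REFERENCE:stimA", 1.0, 1.75),
         ("CR", 1.0, 4.65),
         ("TRIAL:1", 7.0, 7.4),
         ("REFERENCE:stimA", 7.0, 7.75),
         ("CR", 7.0, 7.4)],
        columns=["label", "start", "end"])
    short = pt.Session(rate=session.rate[:, :148], pupil=session.pupil[:148],
                       epochs=rows, meta=session.meta)
    rs2 = pt.extract_reference_responses(short)
    t2 = rs2.table
    assert (t2.loc[t2["trial"] == 1, "reason"] == "truncated").all()
    assert rs2.n_pres == 1


def test_label_pupil_trials_median_split(small_refset):
    labels = pt.label_pupil_trials(small_refset)
    assert set(labels) <= {"large", "small"}
    med = np.median(small_refset.mean_pupil)
    assert np.array_equal(labels == "large", small_refset.mean_pupil > med)
    # ties (constant pupil) go to 'small'
    const = np.ones(5)
    import dataclasses
    rs = dataclasses.replace(small_refset)
    rs.mean_pupil = const
    with pytest.warns(UserWarning):
        lab = pt.label_pupil_trials(rs)
    assert list(lab) == ["small"] * 5


def test_spontaneous_rate_windows(toy_session):
    """s0 averages pre-trial silence and post-blank inter-stimulus gaps."""
    fs = toy_session.fs
    rs = pt.extract_reference_responses(toy_session)
    windows = [(0.65, 1.0), (1.95, 2.45), (3.4, 3.9),   # trial 0
               (6.65, 7.0), (7.95, 8.45)]                # trial 1
    tot = np.zeros(1)
    cnt = 0
    for ws, we in windows:
        sl = bin_slice(ws, we, fs)
        tot += toy_session.rate[:, sl].sum(axis=1)
        cnt += sl.stop - sl.start
    assert np.allclose(rs.s0, tot / cnt)
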