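"""Shared fixtures: small synthetic sessions and a hand-built toy session."""

import numpy as np
import pandas as pd
import pytest

import pupiltask as pt


@pytest.fixture(scope="session")
def small_session():
    """A small mixed-effect synthetic session with its ground truth."""
    cfg = pt.GenerativeConfig(trials_per_block=12, n_units=2,
                              unit_effects=("both", "none"))
    return pt.generate_session(cfg, seed=42)


@pytest.fixture(scope="session")
def small_refset(small_session):
    session, _ = small_session
    return pt.extract_reference_responses(session)


def build_toy_session(n_units=1, fs=20.0):
    """Tiny hand-built session: one passive block, two trials, known epochs.

    Trial 0: refs at 1.0-1.75 and 2.45-3.2 s, target 3.9-4.65 s.
    Trial 1: ref at 7.0-7.75 s, target 8.45-9.2 s.
    """
    dur = 12.0
    n_bins = int(dur * fs)
    rng = np.random.default_rng(0)
    rate = rng.uniform(0, 10, size=(n_units, n_bins))
    pupil = np.full(n_bins, 20.0) + rng.normal(scale=0.5, size=n_bins)
    rows = [
        ("PASSIVE_BLOCK:1", 0.0, dur),
        ("TRIAL:0", 1.0, 4.65),
        ("REFERENCE:stimA", 1.0, 1.75),
        ("REFERENCE:stimB", 2.45, 3.2),
        ("TARGET", 3.9, 4.65),
        ("CR", 1.0, 4.65),
        ("TRIAL:1", 7.0, 9.2),
        ("REFERENCE:stimA", 7.0, 7.75),
        ("TARGET", 8.45, 9.2),
        ("CR", 7.0, 9.2),
    ]
    epochs = pd.DataFrame(rows, columns=["label", "start", "end"])
    meta = dict(session_id="toy", animal="toy", area="A1",
                unit_ids=[f"u{i}" for i in range(n_units)], site="toy-site")
    session = pt.Session(rate=rate, pupil=pupil, epochs=epochs, meta=meta, fs=fs)
    session.validate()
    return session


@pytest.fixture()
def toy_session():
    return build_toy_session()
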