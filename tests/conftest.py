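"""Shared fixtures: small deterministic synthetic trials."""

import numpy as np
import pytest

from vtdmaic.synthetic_trials import (
    default_paperlike_config,
    profile_from_ipd,
    simulate_trial,
)


@pytest.fixture(scope="session")
def paper_trials():
    """One draw of the default paired trials (pooled-mod-like, label-like)."""
    cfg_mod, cfg_label = default_paperlike_config()
    return simulate_trial(cfg_mod), simulate_trial(cfg_label)


@pytest.fixture(scope="session")
def mod_profile(paper_trials):
    mod, _ = paper_trials
    return profile_from_ipd(mod)


@pytest.fixture()
def untied_label(paper_trials):
    """Label trial with unique continuous covariate values and even n.

    Sample medians of untied even-length samples split the sample exactly in
    half, so a trial matched to its own profile gets exactly uniform weights.
    """
    _, label = paper_trials
    frame = label.frame.copy()
    n = len(frame) - (len(frame) % 2)
    frame = frame.iloc[:n].copy()
    jitter = (np.arange(n) + 1) * 1e-4
    frame["age"] = frame["age"].to_numpy() + jitter
    frame["creatinine_clearance"] = (
        frame["creatinine_clearance"].to_numpy() + jitter
    )
    from vtdmaic.trial_data import IPDTable

    return IPDTable(frame.reset_index(drop=True), dict(label.provenance))
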