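import warnings

import numpy as np
import pytest

import splitbelt as sb
from splitbelt.io import RunConfig


@pytest.fixture(scope="session")
def short_trial():
    """One 120-s signal-level trial with ground truth (shared across tests)."""
    cfg = sb.CohortConfig(n_subjects=1, duration=120.0, seed=5)
    subj = sb.generate_subjects(cfg)[0]
    return sb.generate_signal_trial(subj, cfg), cfg


@pytest.fixture(scope="session")
def processed_trial(short_trial):
    trial, cfg = short_trial
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sb.process_trial(trial, RunConfig(seed=cfg.seed))
    return trial, res


@pytest.fixture(scope="session")
def sla_cohort():
    """17-subject measure-level SLA cohort at default noise."""
    cfg = sb.CohortConfig(n_subjects=17, duration=1200.0, seed=11)
    return sb.generate_cohort(cfg, measures=["sla"])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
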