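import numpy as np
import pytest

from imugait import GaitSimParams, simulate_trial

NOISE_FREE = dict(noise_sd_gyr=0.0, noise_sd_acc=0.0)


@pytest.fixture(scope="session")
def clean_trial():
    """A 20-stride noise-free generator trial with exact ground truth."""
    return simulate_trial(GaitSimParams(n_strides=20, seed=1, **NOISE_FREE))


def event_errors(events, truth, kind, max_lag=0.25):
    """(n_recovered, |error| array in s) of truth events of one kind.

    A truth event counts as recovered when a detected event of the same kind
    lies within ``max_lag``.
    """
    det = events.times(kind)
    errs = []
    for t in truth.times(kind):
        if len(det) == 0:
            continue
        d = float(np.min(np.abs(det - t)))
        if d <= max_lag:
            errs.append(d)
    return len(errs), np.asarray(errs)
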