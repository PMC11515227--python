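import numpy as np
import pytest

from ipbkit import StudyEffect


def make_effects(y, se, n=None, events=None, nonevents=None, prefix="s"):
    """Build StudyEffects from parallel sequences, with sensible covariates.

    When n/events/nonevents are omitted they are derived from se so that
    Peters' regressors vary across studies.
    """
    y = list(map(float, y))
    se = list(map(float, se))
    k = len(y)
    if n is None:
        n = [max(4.0, round(4.0 / s**2)) for s in se]  # larger study <-> smaller se
    if events is None:
        events = [max(1.0, round(0.1 * ni)) for ni in n]
    if nonevents is None:
        nonevents = [ni - ei for ni, ei in zip(n, events)]
    return [
        StudyEffect(f"{prefix}{i + 1}", y[i], se[i], n[i], events[i], nonevents[i])
        for i in range(k)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def five_study_fixture():
    """Printed 5-study set used against the least-squares oracles."""
    return make_effects(
        y=[0.12, -0.35, 0.51, 0.08, 0.70],
        se=[0.11, 0.23, 0.31, 0.42, 0.52],
        n=[320, 180, 95, 60, 44],
        events=[30, 22, 11, 9, 6],
    )
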