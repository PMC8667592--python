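"""Shared fixtures: default promoter, canonical regimes and generators."""

import numpy as np
import pytest

import tfmodes as tm
from tfmodes.studies import (  # noqa: F401  (re-exported for tests)
    REGIMES,
    abundance_grid,
    manifold_pairs_from_truth,
    regime_truth,
)

# alias kept for readability in tests
manifold_dataset_from_truth = manifold_pairs_from_truth


@pytest.fixture(scope="session")
def promoter() -> tm.PromoterParameters:
    return tm.PromoterParameters()


@pytest.fixture(scope="session")
def P(promoter) -> float:
    return promoter.P


def random_parameter_draw(rng: np.random.Generator):
    """A random but physically sensible (promoter, tf) parameter pair."""
    pr = tm.PromoterParameters(
        n_p=float(rng.uniform(50, 5000)),
        delta_eps_p=float(rng.uniform(-9, -2)),
        n_ns=4.6e6)
    tf = tm.TFRegulatoryParameters(
        alpha=float(rng.lognormal(0, 1.5)),
        beta=float(rng.lognormal(0, 1.5)),
        delta_eps_tf=float(rng.uniform(-9, 0)))
    return pr, tf
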