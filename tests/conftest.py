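"""Shared fixtures: reference circuits, tuned gains, and the one fitted
unintuitive circuit reused across fitting / simulation / acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cxsteer import (FitConfig, build_fly, build_rule_breaker, build_uniform,
                     fit_unintuitive, tune_gain)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: study conditions of the unintuitive-circuit fit used throughout the
#: suite: one seeded differential-evolution run at desk scale
FIT_CONFIG = FitConfig(seed=1)


@pytest.fixture(scope="session")
def uniform_circuits():
    return {n: build_uniform(n) for n in (3, 5, 8, 21)}


@pytest.fixture(scope="session")
def fly_circuit():
    return build_fly()


@pytest.fixture(scope="session")
def rule_breakers():
    return {w: build_rule_breaker(w)
            for w in ("rule1", "rule4", "rule5", "rule1and5")}


@pytest.fixture(scope="session")
def fit_result():
    """The seeded differential-evolution fit of the unintuitive template."""
    return fit_unintuitive(config=FIT_CONFIG)


def tuned(spec):
    """Circuit with its output gain tuned to the 50-60 deg/s band."""
    return spec.with_gain(tune_gain(spec))


@pytest.fixture(scope="session")
def tuned_cache():
    """Memoised gain tuning keyed by builder provenance."""
    cache = {}

    def get(spec, key):
        if key not in cache:
            cache[key] = spec.with_gain(tune_gain(spec))
        return cache[key]

    return get
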