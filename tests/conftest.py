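"""Shared fixtures: parameter sets and cached simulation runs.

Rebound runs are the expensive shared resource, so they are computed lazily
once per session and memoized by (profile label, temperature tag).
"""

from __future__ import annotations

import pytest

from tburst import default_neuron, make_synthetic_cat, temperature_transform, with_cat
from tburst.experiments import run_rebound_experiment


@pytest.fixture(scope="session")
def baseline():
    return default_neuron()


@pytest.fixture(scope="session")
def rebound_runs(baseline):
    """Memoized standard rebound runs keyed by (profile, 'cold'|'warm'|None).

    ``get(None)`` is the no-CaT control; ``get(label)`` inserts the profile's
    synthetic CaT; ``get(label, warm=True)`` applies the default temperature
    transform first.
    """
    cache = {}

    def get(label=None, warm=False):
        key = (label, warm)
        if key not in cache:
            if label is None:
                params = baseline
            else:
                cat = make_synthetic_cat(label)
                if warm:
                    cat = temperature_transform(cat)
                params = with_cat(baseline, cat)
            cache[key] = run_rebound_experiment(params)
        return cache[key]

    return get
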