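"""Shared fixtures: small but complete simulated experiments.

Fixtures are session-scoped; everything is generated programmatically from
fixed seeds so the suite needs no data files.
"""

import numpy as np
import pytest

from mcdi import (
    MCDIAnalysis,
    build_protocol,
    generate_all_ensembles,
    make_ln_neuron,
    make_lnln_neuron,
    make_null_neuron,
    make_patch_neuron,
    simulate_session,
)


@pytest.fixture(scope="session")
def small_ensembles():
    """All seven ensembles at 128 examples (16x16)."""
    return generate_all_ensembles(n_examples=128, seed=101)


@pytest.fixture(scope="session")
def small_protocol():
    return build_protocol(n_examples_per_set=128, n_repeats=2, interleave_seed=7)


@pytest.fixture(scope="session")
def lnln_session(small_ensembles, small_protocol):
    return simulate_session(make_lnln_neuron(), small_ensembles, small_protocol, seed=11)


@pytest.fixture(scope="session")
def ln_session(small_ensembles, small_protocol):
    return simulate_session(make_ln_neuron(), small_ensembles, small_protocol, seed=12)


@pytest.fixture(scope="session")
def null_session(small_protocol):
    return simulate_session(make_null_neuron(10.0), None, small_protocol, seed=13)


@pytest.fixture(scope="session")
def lnln_results(lnln_session):
    return MCDIAnalysis(lnln_session, n_surrogates=500).fit(seed=21)


@pytest.fixture(scope="session")
def rf_ensembles():
    """Full-size ensembles for receptive-field recovery (1024 examples)."""
    return generate_all_ensembles(n_examples=1024, seed=202)


@pytest.fixture(scope="session")
def patch_session(rf_ensembles):
    proto = build_protocol(n_examples_per_set=1024, n_repeats=2, interleave_seed=9)
    neuron = make_patch_neuron(origin=(6, 6), size=3, baseline_rate_hz=10, peak_rate_hz=40)
    return simulate_session(neuron, rf_ensembles, proto, seed=31)
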