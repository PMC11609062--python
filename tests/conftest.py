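import numpy as np
import pytest

import emgsynergy as es
from emgsynergy.types import N_POINTS


@pytest.fixture(scope="session")
def default_sim():
    """One default two-condition dataset, shared across tests (seed 1)."""
    return es.simulate_cycles(es.default_spec(seed=1))


@pytest.fixture(scope="session")
def tiny_spec():
    """A light 3-synergy spec for fast end-to-end style tests."""
    shared = [
        es.GroundTruthSynergy(
            "early", _weights(RF=1.0, VL=0.3, VM=0.25, BF=0.1), -300.0, 0.5
        ),
        es.GroundTruthSynergy(
            "mid", _weights(TA=1.0, EDL=0.5, EDB=0.2, BF=0.25), -50.0, 0.4
        ),
        es.GroundTruthSynergy(
            "late", _weights(GAS=1.0, SOL=0.8, PL=0.3, VM=0.15), 100.0, 0.6
        ),
    ]
    return es.SyntheticSpec(
        synergies_shared=shared,
        synergies_specific_a=[],
        synergies_specific_b=[],
        n_cycles_a=24,
        n_cycles_b=12,
        snr=20.0,
        seed=7,
    )


def _weights(**kw):
    v = np.zeros(len(es.MUSCLES))
    for k, x in kw.items():
        v[es.MUSCLES.index(k)] = x
    return v


@pytest.fixture
def rank3_cycles(tiny_spec):
    """Noiseless, jitter-free rank-3 cycles (exact low-rank structure)."""
    from dataclasses import replace

    spec = replace(tiny_spec, snr=None, cycle_amp_sigma=0.3, cycle_time_jitter_ms=0.0)
    # amplitude jitter keeps cycles distinct but each cycle stays in the
    # span of the three fixed spatio-temporal modes
    return es.simulate_cycles(spec)


def make_weights(**kw):
    return _weights(**kw)
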