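import pytest

from switchjoint.simulate import SimParams, make_synthetic_locus, sample_events


@pytest.fixture(scope="session")
def small_sim():
    """Small error-free simulation shared across tests: locus + 60 events."""
    params = SimParams(
        seed=101, n_events=60, error_sub_rate=0.0, error_indel_rate=0.0,
        depth_min=3, depth_max=6,
    )
    record, locus = make_synthetic_locus(params)
    reference = str(record.seq)
    events = sample_events(params, locus, reference)
    return params, reference, locus, events


@pytest.fixture(scope="session")
def locus60(small_sim):
    return small_sim[2]


@pytest.fixture(scope="session")
def reference60(small_sim):
    return small_sim[1]
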