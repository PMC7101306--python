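import pytest

import tdarx as T


@pytest.fixture(scope="session")
def rules():
    return T.default_rules()


@pytest.fixture(scope="session")
def palette():
    return T.default_palette()


@pytest.fixture(scope="session")
def layout():
    return T.default_layout()


@pytest.fixture(scope="session")
def small_cohort():
    """50 mixed-label synthetic records (testing-cohort profile)."""
    records, _ = T.generate_cohort(10, 40, seed=1001, profile="testing")
    return records


@pytest.fixture(scope="session")
def cohort1000():
    """1000 randomized valid records drawn across both classes."""
    records, _ = T.generate_cohort(300, 700, seed=505)
    return records


@pytest.fixture(scope="session")
def acpa_only_cohort():
    """Cohort whose classes are identical except for the ACPA value."""
    records, _ = T.generate_cohort(100, 100, seed=9, separation=0.0)
    for r in records:
        r.acpa = 100.0 if r.label == "RA" else 0.0
    return records[:160], records[160:]
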