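import numpy as np
import pytest

from irespred.records import make_record
from irespred.simulate import MotifSpec, SyntheticConfig, generate_library


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_records():
    """Six hand-made records across three groups, threshold 1.0."""
    rows = [
        ("s1", "AUGCAUGCAUGCAUGCAUGC", "dsrna", 2.5),
        ("s2", "UUUUUUUUUUGGGGGGGGGG", "dsrna", 0.4),
        ("s3", "ACGUACGUACGUACGUACGU", "retro", 1.7),
        ("s4", "CCCCCCCCCCCCCCCCCCCC", "retro", 0.2),
        ("s5", "AAAAAAAAAAAAAAAAAAAA", "human_5utr", 0.9),
        ("s6", "GCGCGCGCGCGCGCGCGCGC", "human_5utr", 3.1),
    ]
    return [make_record(i, s, g, a, threshold=1.0) for i, s, g, a in rows]


@pytest.fixture(scope="session")
def small_library():
    """One-group synthetic library small enough for fast model tests."""
    cfg = SyntheticConfig(
        n=400,
        seed=20,
        recipes={
            "dsrna": [
                MotifSpec("UUUU", +1.0, center=-50, width=20.0),
                MotifSpec("AAAA", -0.8, center=None),
            ]
        },
    )
    records, truth, floor = generate_library(cfg)
    return records, truth, floor
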