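"""Shared fixtures: the printed worked-example data and small helpers."""

import pytest

from refcomp import MatchedEntity

# Two-chromosome worked example: X is the reference, Y the target.
EXAMPLE_X = ">X_chr1.fa\nAGCTGGGCCCTTaaggNNNnnnXXX\nTTTCCCGGGAAAaaaTTTccctttg\n"
EXAMPLE_Y = ">Y_chr1.fa\nAGCTGGGCCCTTaaggtttnnnXXX\nTTTCCCGGGNNNaaaTTTccctttg\n"

# Six 20-base B sequences: R1 is the first-level reference, T1..T5 targets.
R1 = "AGATGGGCCCTTTAGGTATT"
B_ROWS = {
    "T1": "AGCTGGTCCCTGAAGGAATC",
    "T2": "AGCTGGTCCCTGGAGGAATC",
    "T3": "AGTTGGTCCCTGGAGGATTT",
    "T4": "AGTTGGTCCCTGAAGGATTT",
    "T5": "ATATGGTCCCTGAAGGATTT",
}

# First-level entity streams for T1..T5 (position 1-based in R1).
ENTITY_ROWS = {
    "T1": [(1, 2, "C"), (4, 3, "T"), (8, 4, "GA"), (14, 3, "A"), (18, 2, "C")],
    "T2": [(1, 2, "C"), (4, 3, "T"), (8, 4, "GG"), (14, 3, "A"), (18, 2, "C")],
    "T3": [(1, 2, "T"), (4, 3, "T"), (8, 4, "GG"), (14, 3, "AT"), (19, 2, "")],
    "T4": [(1, 2, "T"), (4, 3, "T"), (8, 4, "GA"), (14, 3, "AT"), (19, 2, "")],
    "T5": [(1, 1, "T"), (3, 4, "T"), (8, 4, "GA"), (14, 3, "AT"), (19, 2, "")],
}


@pytest.fixture
def entity_streams():
    return [
        [MatchedEntity(*e) for e in ENTITY_ROWS[name]]
        for name in ("T1", "T2", "T3", "T4", "T5")
    ]
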