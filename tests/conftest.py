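import numpy as np
import pytest

from dtimage.aaindex import AMINO_ACIDS, AAIndexProperty, PropertySet

AAINDEX_FIXTURE = """\
H TEST0001
D hydropathy-like synthetic scale
R PMID:0000000
A Nobody, A.
T A synthetic fixture record
J Nowhere 1 (2020)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.80   -4.50   -3.50   -3.50    2.50   -3.50   -3.50   -0.40   -3.20    4.50
    3.80   -3.90    1.90    2.80   -1.60   -0.80   -0.70   -0.90   -1.30    4.20
//
H TEST0002
D bulkiness-like synthetic scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   11.50   14.28   12.82   11.68   13.46   14.45   13.57    3.40   13.69   21.40
   21.40   15.71   16.25   19.80   17.43    9.47   15.77   21.67   18.03   21.57
//
"""

AAINDEX_WITH_NA = """\
H TEST0003
D scale with a missing value
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.00    2.00      NA    4.00    5.00    6.00    7.00    8.00    9.00   10.00
   11.00   12.00   13.00   14.00   15.00   16.00   17.00   18.00   19.00   20.00
//
"""


def make_property(accession: str, values) -> AAIndexProperty:
    return AAIndexProperty(
        accession=accession,
        description="test scale",
        values=dict(zip(AMINO_ACIDS, [float(v) for v in values])),
    )


@pytest.fixture
def aaindex_text() -> str:
    return AAINDEX_FIXTURE


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def two_properties(rng) -> PropertySet:
    p1 = make_property("FIX0001", rng.standard_normal(20))
    p2 = make_property("FIX0002", rng.standard_normal(20))
    return PropertySet((p1, p2), threshold=1.0)


def random_sequence(rng, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
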