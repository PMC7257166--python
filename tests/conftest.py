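import pytest

from xgox.simulate import SpectrumNoiseModel

# Published C4-oxidized product annotations from the two characterized
# digests: the substitution-intolerant enzyme leaves oxidized unbranched G
# termini, the tolerant one mostly substituted (X/L) termini.  Partially
# resolved entries (known terminus, composition-level remainder) are tallied
# by their terminus; composition-only entries are counted separately.
INTOLERANT_DIGEST_STRUCTURES = [
    "O4k:GXXX",
    "O4k:XXXG",
    "O4k:GXLX",
    "O4k:GXXL",
    "O4k:GLXX",
    "O4k:X",  # terminus-resolved, remainder composition-level (H4P2)
    "O4k:G",  # terminus-resolved, remainder composition-level (H5P3)
]
INTOLERANT_COMPOSITION_ONLY = 1  # Ox-H6P4

TOLERANT_DIGEST_STRUCTURES = [
    "O4k:GX",
    "O4k:XG",
    "O4k:XXG",
    "O4k:XGX",
    "O4k:XGL",
    "O4k:GLX",
    "O4k:LGX",
    "O4k:XXGX",
    "O4k:XGXX",
    "O4k:LLG",
    "O4k:LGL",
    "O4k:XGXL",
    "O4k:XGLX",
    "O4k:LXGX",
    "O4k:XGLL",
]
TOLERANT_COMPOSITION_ONLY = 2  # Ox-H6P3, Ox-H6P4


@pytest.fixture
def intolerant_structures():
    return list(INTOLERANT_DIGEST_STRUCTURES)


@pytest.fixture
def tolerant_structures():
    return list(TOLERANT_DIGEST_STRUCTURES)


@pytest.fixture
def noiseless():
    return SpectrumNoiseModel.noiseless()
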