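import random

import pytest

from baitsfinder.records import (
    NUCLEOTIDE,
    PROTEIN,
    SequenceRecord,
    translate,
)
from baitsfinder.simulate import SimulationConfig, generate_study

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = [
    a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS
]


def random_cds(rng: random.Random, n_codons: int) -> str:
    return "".join(rng.choice(_SENSE) for _ in range(n_codons))


def mutate_nt(rng: random.Random, seq: str, rate: float) -> str:
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in _BASES if b != c]))
        else:
            out.append(c)
    return "".join(out)


@pytest.fixture(scope="session")
def zero_divergence_study():
    """Small planted study with all mutation processes switched off."""
    taxa = ("LiPh", "TrVe", "StHe", "OrAe")
    config = SimulationConfig(
        seed=11,
        n_scg=8,
        n_paralog_pairs=2,
        divergence={t: 0.0 for t in taxa},
        n_host_contaminants=3,
        n_plastid_transcripts=2,
    )
    return generate_study(config)


@pytest.fixture
def rng():
    return random.Random(20240917)
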