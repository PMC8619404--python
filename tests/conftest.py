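import numpy as np
import pytest

from neurotoxaug import (
    AugmentationParams,
    FamilySpec,
    Label,
    PeptideRecord,
    PhyschemGroups,
    ScoringScheme,
    make_benchmark,
)
from neurotoxaug.pepcore import CANONICAL_AA


@pytest.fixture(scope="session")
def groups() -> PhyschemGroups:
    return PhyschemGroups()


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_benchmark():
    """A tiny but homology-rich benchmark: 5 families x 8 members."""
    spec = FamilySpec(n_families=5, members_per_family=8, neg_count=100, seed=11)
    return make_benchmark(spec)


@pytest.fixture
def random_peptide():
    def _make(length: int, seed: int = 0, pid: str = "pep",
              label: Label = Label.UNKNOWN) -> PeptideRecord:
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(CANONICAL_AA), size=length))
        return PeptideRecord(id=pid, sequence=seq, label=label)

    return _make


@pytest.fixture(scope="session")
def fixed_seed_peptide() -> PeptideRecord:
    """A fixed 100-residue seed used for sampler-rate measurements."""
    rng = np.random.default_rng(2024)
    seq = "".join(rng.choice(list(CANONICAL_AA), size=100))
    return PeptideRecord(id="seed100", sequence=seq, label=Label.NEUROTOXIC)


@pytest.fixture
def default_params() -> AugmentationParams:
    return AugmentationParams()
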