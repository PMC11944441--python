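from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from ampredkit import AlignmentParams, SequenceDatabase, validate_database
from ampredkit.synthetic import AA20, SyntheticDbSpec, generate_peptide_db


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240317)


@pytest.fixture
def exhaustive_params() -> AlignmentParams:
    return AlignmentParams(mode="exhaustive")


@pytest.fixture
def permissive_params() -> AlignmentParams:
    """Exhaustive search that records everything with a positive score."""
    return AlignmentParams(mode="exhaustive", evalue_cutoff=1e9)


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


@pytest.fixture
def small_validated_db() -> SequenceDatabase:
    """40 peptides (length 15-50) with 20% planted exact duplicates."""
    spec = SyntheticDbSpec(
        n_sequences=40, length_range=(15, 50), duplicate_fraction=0.2,
        seed=7, name="selfdb",
    )
    db, _ = generate_peptide_db(spec)
    return validate_database(db)
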