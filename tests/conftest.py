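import numpy as np
import pytest

from subfamkit.io import SequenceRecord
from subfamkit.msa import Alignment
from subfamkit.pairwise import ScoringScheme
from subfamkit.simulate import FamilySpec, MotifInjection, simulate_family


@pytest.fixture(scope="session")
def scheme():
    """Default BLOSUM62 scoring scheme (loaded once per session)."""
    return ScoringScheme()


@pytest.fixture(scope="session")
def simple_scheme():
    return ScoringScheme.simple(match=1, mismatch=-1, gap_open=1, gap_extend=1)


@pytest.fixture(scope="session")
def small_family():
    """A small planted family: 4 subfamilies x 4 leaves, 120 columns."""
    return simulate_family(
        FamilySpec(n_subfamilies=4, leaves_per_subfamily=4, length=120, seed=11)
    )


@pytest.fixture(scope="session")
def motif_family():
    """Planted family with a cofactor-style fingerprint per subfamily."""
    spec = FamilySpec(
        n_subfamilies=3,
        leaves_per_subfamily=5,
        length=200,
        seed=23,
        invariant_columns={10: "R", 40: "E", 70: "H"},
        motif_injections=(
            MotifInjection(0, 100, "DAAAA"),  # aspartate at the key position
            MotifInjection(1, 100, "TRSAK"),  # NADP(H)-style fingerprint
            MotifInjection(2, 100, "GGGGG"),  # neither signal
        ),
    )
    return simulate_family(spec)


def make_alignment(rows: dict[str, str]) -> Alignment:
    return Alignment.from_records(
        [SequenceRecord(rid, seq) for rid, seq in rows.items()]
    )


def random_protein(rng: np.random.Generator, length: int) -> str:
    from subfamkit.io import AA20

    return "".join(rng.choice(list(AA20), size=length))
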