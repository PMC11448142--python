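import numpy as np
import pytest

from ampliscope.binding import SearchParams
from ampliscope.synthetic_data import (
    PairPlant,
    PlantSpec,
    SynthSpec,
    example_primer_panel,
    generate_reference_set,
)


@pytest.fixture(scope="session")
def panel():
    """Synthetic primer panel mirroring a comammox amoA assay layout."""
    primers, pairs = example_primer_panel()
    return primers, pairs


@pytest.fixture(scope="session")
def params():
    return SearchParams()


@pytest.fixture(scope="session")
def planted_db(panel):
    """Reference set with planted per-group coverage fractions
    {0.7 at 0 MM, +0.2 at 2 MM} for cladeA, 1.0 for cladeB, 0.5 at 2 MM for
    AOB, nothing in other_cu_mmo -- plus planted amplicons for the three
    assay pairs."""
    primers, pairs = panel
    spec = SynthSpec(
        seed=20260929,
        groups={"cladeA": 10, "cladeB": 10, "AOB": 6, "other_cu_mmo": 10},
        seq_len=(700, 860),
        plants=[
            # single-primer plants use (primer, group) combinations that the
            # pair plants below do not touch, so the per-primer coverage
            # fractions stay exactly as written here
            PlantSpec("cladeA", "mixA_377F", 0.7, 0, ()),
            PlantSpec("cladeA", "mixA_377F", 0.2, 2, (5, 9)),
            PlantSpec("cladeB", "comx_359R", 1.0, 0, ()),
            PlantSpec("AOB", "comx_162F", 0.5, 2, (4, 8)),
        ],
        pair_plants=[
            PairPlant("cladeA", "cladeA_long", 0.9, 415),
            PairPlant("cladeA", "comx_pair", 0.5, 198),
            PairPlant("cladeB", "cladeB_short", 0.8, 235, r_mm_positions=(4,)),
        ],
    )
    db, truth = generate_reference_set(spec, primers, pairs)
    return db, truth, spec


def random_iupac(rng: np.random.Generator, length: int, p_ambig: float = 0.15) -> str:
    """Random IUPAC string, mostly concrete bases with occasional
    degenerate codes (the realistic shape of a degenerate primer)."""
    plain = "ACGT"
    ambig = "RYSWKMBDHVN"
    out = []
    for _ in range(length):
        if rng.random() < p_ambig:
            out.append(ambig[rng.integers(len(ambig))])
        else:
            out.append(plain[rng.integers(4)])
    return "".join(out)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
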