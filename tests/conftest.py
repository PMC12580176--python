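import numpy as np
import pytest

from epitoscan.catalog import AllergenEntry, Completeness, parse_allergen_designation
from epitoscan.epitopes import EpitopeRecord, EpitopeSet, EpitopeType, Polarity

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def make_entry(
    designation=None,
    biochemical_name="β-parvalbumin (PVB)",
    species="Gadus morhua",
    accessions=None,
    sequence=None,
    completeness=None,
    sources=("who_iuis",),
    pmids=(),
):
    """Entry factory with sensible defaults for tests."""
    if completeness is None:
        completeness = Completeness.COMPLETE if sequence else Completeness.ABSENT
    return AllergenEntry(
        designation=parse_allergen_designation(designation) if designation else None,
        biochemical_name=biochemical_name,
        species_latin=species,
        accessions=accessions or ({} if designation else {"uniprot": "P00000"}),
        sequence=sequence,
        completeness=completeness,
        source_flags={s: True for s in sources},
        pmids=pmids,
    )


def make_epitope_set(peptides, polarity=Polarity.POSITIVE):
    records = tuple(
        EpitopeRecord(p, polarity, EpitopeType.LINEAR, "test", (f"a{i}",))
        for i, p in enumerate(peptides)
    )
    return EpitopeSet(records, polarity)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_sequence(rng, length):
    return "".join(rng.choice(list(RESIDUES), size=length))
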