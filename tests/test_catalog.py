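"""Catalog curation: nomenclature parsing, dedup, filtering, sensitivity."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epitoscan.catalog import (
    AllergenDesignation,
    CatalogError,
    Completeness,
    DesignationParseError,
    ToolOutcome,
    compute_sensitivity,
    database_overlap,
    deduplicate_entries,
    entry_key,
    filter_complete,
    has_nonstandard_residues,
    parse_allergen_designation,
    select_primary_accession,
    summarize_families,
)

from conftest import make_entry


class TestDesignationParsing:
    @pytest.mark.parametrize(
        "name, base, iso, var",
        [
            ("Gad m 1.0101", "Gad m 1", "01", "01"),
            ("Gad m 1.0102", "Gad m 1", "01", "02"),
            ("Clu h 1.01", "Clu h 1", "01", None),
            ("Sar sa 1.0101", "Sar sa 1", "01", "01"),
            ("Cyp c 1", "Cyp c 1", None, None),
        ],
    )
    def test_splits_per_nomenclature(self, name, base, iso, var):
        d = parse_allergen_designation(name)
        assert (d.allergen_base, d.isoallergen_code, d.variant_code) == (base, iso, var)

    def test_normalizes_spacing_and_case(self):
        assert str(parse_allergen_designation("gad  M   1.01")) == "Gad m 1.01"

    @pytest.mark.parametrize(
        "bad",
        ["parvalbumin", "Gad m", "Gad m 1.011", "Gad m 1.01012", "Gad m x.01", ""],
    )
    def test_malformed_names_raise(self, bad):
        with pytest.raises(DesignationParseError):
            parse_allergen_designation(bad)

    def test_variant_requires_isoallergen(self):
        with pytest.raises(CatalogError):
            AllergenDesignation("Gad m 1", None, "01")

    @given(
        genus=st.text(st.characters(min_codepoint=97, max_codepoint=122), min_size=3, max_size=4),
        species=st.text(st.characters(min_codepoint=97, max_codepoint=122), min_size=1, max_size=2),
        number=st.integers(min_value=1, max_value=99),
        iso=st.one_of(st.none(), st.integers(min_value=1, max_value=99)),
        var=st.one_of(st.none(), st.integers(min_value=1, max_value=99)),
    )
    @settings(max_examples=200, derandomize=True)
    def test_format_parse_roundtrip(self, genus, species, number, iso, var):
        if iso is None:
            var = None
        name = f"{genus.capitalize()} {species} {number}"
        if iso is not None:
            name += f".{iso:02d}" + (f"{var:02d}" if var is not None else "")
        assert str(parse_allergen_designation(name)) == name


class TestAccessionPriority:
    def test_uniprot_beats_refseq(self):
        e = make_entry(accessions={"uniprot": "B5DGM7", "refseq": "XP_1"}, sources=("compare",))
        assert select_primary_accession(e) == ("uniprot", "B5DGM7")

    def test_single_accession_returned(self):
        e = make_entry(accessions={"refseq": "XP_026771637.1"})
        assert select_primary_accession(e) == ("refseq", "XP_026771637.1")

    def test_no_accession_errors(self):
        e = make_entry(designation="Gad m 1.0101", accessions={})
        with pytest.raises(CatalogError):
            select_primary_accession(e)


class TestDeduplication:
    def test_three_rows_one_variant_merge(self):
        # one variant listed under three different sequence IDs
        rows = [
            make_entry("Sal s 1.0101", accessions={"uniprot": "Q91482"}, sources=("who_iuis",)),
            make_entry("Sal s 1.0101", accessions={"refseq": "NP_001117014"}, sources=("allergenonline",)),
            make_entry("Sal s 1.0101", accessions={"genbank_protein": "ACI66930"}, sources=("compare",)),
        ]
        merged = deduplicate_entries(rows)
        assert len(merged) == 1
        e = merged[0]
        assert e.accessions == {
            "uniprot": "Q91482",
            "refseq": "NP_001117014",
            "genbank_protein": "ACI66930",
        }
        assert e.sources == {"who_iuis", "allergenonline", "compare"}

    def test_distinct_designations_kept(self):
        rows = [make_entry("Gad m 1.0101"), make_entry("Gad m 1.0102")]
        assert len(deduplicate_entries(rows)) == 2

    def test_unassigned_rows_keyed_by_accession(self):
        rows = [make_entry(accessions={"uniprot": "P02620"})] * 2
        merged = deduplicate_entries(rows)
        assert len(merged) == 1
        assert entry_key(merged[0]) == "P02620"

    def test_conflicting_sequences_error(self):
        rows = [
            make_entry("Gad m 1.0101", sequence="ACDE"),
            make_entry("Gad m 1.0101", sequence="ACDF"),
        ]
        with pytest.raises(CatalogError, match="Gad m 1.0101"):
            deduplicate_entries(rows)

    def test_idempotent(self):
        rows = [
            make_entry("Gad m 1.0101", sources=("who_iuis",)),
            make_entry("Gad m 1.0101", sources=("allergome",)),
            make_entry(accessions={"uniprot": "P02620"}),
        ]
        once = deduplicate_entries(rows)
        assert deduplicate_entries(once) == once

    def test_pmids_unioned(self):
        rows = [
            make_entry("Gad m 1.0101", pmids=("111", "222")),
            make_entry("Gad m 1.0101", pmids=("222", "333")),
        ]
        assert deduplicate_entries(rows)[0].pmids == ("111", "222", "333")


class TestFilteringAndOverlap:
    def test_filter_complete_counts_and_order(self):
        rows = [
            make_entry(f"Gad m {i}", sequence="ACDE" if i <= 4 else None)
            for i in range(1, 11)
        ]
        kept = filter_complete(rows)
        assert len(kept) == 4
        assert [str(e.designation) for e in kept] == [
            str(e.designation) for e in rows if e.completeness is Completeness.COMPLETE
        ]

    def test_all_partial_gives_empty(self):
        rows = [make_entry("Gad m 1.0101", sequence="ACDE", completeness=Completeness.PARTIAL)]
        assert filter_complete(rows) == []

    def test_overlap_cells_and_sum(self):
        rows = [
            make_entry("Gad m 1.0101", sources=("who_iuis",)),
            make_entry("Gad m 1.0102", sources=("who_iuis", "allergome")),
            make_entry("Gad m 1.0201", sources=("who_iuis", "allergome", "compare", "allergenonline")),
        ]
        cells = database_overlap(rows)
        assert len(cells) == 3 and all(v == 1 for v in cells.values())
        assert sum(cells.values()) == len(rows)
        assert cells[frozenset({"who_iuis", "allergome", "compare", "allergenonline"})] == 1

    def test_overlap_counts_sum_property(self, rng):
        import itertools

        combos = [c for r in range(1, 5) for c in itertools.combinations(
            ("who_iuis", "allergenonline", "compare", "allergome"), r)]
        rows = [
            make_entry(f"Gad m {i + 1}", sources=combos[rng.integers(0, len(combos))])
            for i in range(40)
        ]
        assert sum(database_overlap(rows).values()) == 40


class TestFamilySummaries:
    def test_partition_by_assignment_and_species(self):
        rows = [
            make_entry("Gad m 1.0101", species="Gadus morhua", sequence="ACDE"),
            make_entry("Gad m 1.0102", species="Gadus morhua", sequence="ACDE"),
            make_entry(accessions={"uniprot": "P02620"}, species="Merluccius merluccius",
                       sequence="ACDE"),
            make_entry("Sal s 2.0101", biochemical_name="β-enolase",
                       species="Salmo salar", sequence="MKLV"),
        ]
        summary = summarize_families(rows)
        pvb = summary["β-parvalbumin (PVB)"]
        assert (pvb.total, pvb.iuis_assigned, pvb.unassigned, pvb.n_species) == (3, 2, 1, 2)
        assert summary["β-enolase"].total == 1

    def test_totals_equal_input_size(self, rng):
        families = ["β-parvalbumin (PVB)", "Tropomyosin", "Aldolase A"]
        rows = [
            make_entry(f"Gad m {i + 1}", biochemical_name=families[rng.integers(0, 3)],
                       sequence="ACDE")
            for i in range(25)
        ]
        assert sum(s.total for s in summarize_families(rows).values()) == 25


class TestSensitivity:
    def test_published_style_arithmetic(self):
        # 66 of 79 detected -> 83.5; 74 of 79 -> 93.7
        def outcomes(detected, total):
            return [ToolOutcome(f"e{i}", i < detected) for i in range(total)]

        assert compute_sensitivity(outcomes(66, 79)) == 83.5
        assert compute_sensitivity(outcomes(74, 79)) == 93.7

    def test_all_detected(self):
        assert compute_sensitivity([ToolOutcome("e", True)] * 5) == 100.0

    def test_empty_errors(self):
        with pytest.raises(CatalogError):
            compute_sensitivity([])

    def test_rejected_cannot_be_detected(self):
        with pytest.raises(CatalogError):
            ToolOutcome("e", detected=True, rejected_nonstandard=True)

    def test_monotone_in_rejections(self):
        base = [ToolOutcome(f"e{i}", True) for i in range(10)]
        prev = compute_sensitivity(base)
        for k in range(1, 11):
            flipped = [
                ToolOutcome(f"e{i}", False, rejected_nonstandard=True) if i < k else o
                for i, o in enumerate(base)
            ]
            cur = compute_sensitivity(flipped)
            assert cur <= prev
            prev = cur

    def test_rounding_half_up(self):
        # 1/3 detected = 33.33..% -> 33.3; 2/3 = 66.66..% -> 66.7
        assert compute_sensitivity(
            [ToolOutcome("a", True), ToolOutcome("b", False), ToolOutcome("c", False)]
        ) == 33.3
        assert compute_sensitivity(
            [ToolOutcome("a", True), ToolOutcome("b", True), ToolOutcome("c", False)]
        ) == 66.7

    def test_nonstandard_residue_detection(self):
        assert has_nonstandard_residues("ACDEXF")
        assert not has_nonstandard_residues("acdef")


def test_catalog_roundtrip_io(tmp_path):
    from epitoscan.catalog import read_catalog, write_catalog

    rows = [
        make_entry("Gad m 1.0101", sequence="ACDEFGHIK", pmids=("111",),
                   sources=("who_iuis", "allergome")),
        make_entry(accessions={"refseq": "XP_1"}, sequence=None),
    ]
    path = tmp_path / "catalog.tsv"
    write_catalog(rows, path)
    back = read_catalog(path)
    assert back == rows
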