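"""Curation of fish isoallergen/variant catalog entries.

Allergen databases (WHO/IUIS, AllergenOnline, COMPARE, Allergome) export
overlapping, inconsistently keyed tables of isoallergens and variants.  This
module provides the data model for one catalog row, WHO/IUIS nomenclature
parsing ("Gad m 1.0101" = allergen "Gad m 1", isoallergen 01, variant 01),
deduplication with accession-priority keying, completeness filtering,
database-overlap accounting, per-family summaries, and the sensitivity
arithmetic used to score allergenicity prediction tools against a panel of
known allergens.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "SOURCE_DATABASES",
    "ACCESSION_KINDS",
    "CANONICAL_RESIDUES",
    "CatalogError",
    "DesignationParseError",
    "Completeness",
    "AllergenDesignation",
    "AllergenEntry",
    "ToolOutcome",
    "FamilySummary",
    "parse_allergen_designation",
    "select_primary_accession",
    "entry_key",
    "deduplicate_entries",
    "filter_complete",
    "database_overlap",
    "summarize_families",
    "compute_sensitivity",
    "has_nonstandard_residues",
    "read_catalog",
    "write_catalog",
    "entries_to_fasta",
]

#: The four source allergen databases, in conventional order.
SOURCE_DATABASES = ("who_iuis", "allergenonline", "compare", "allergome")

#: Accession kinds in priority order for picking a primary accession.
#: UniProt is preferred, then RefSeq, then GenBank protein, then PDB; a
#: GenBank nucleotide accession is accepted only as a last resort so that
#: nucleotide-only rows still obtain a stable key.
ACCESSION_KINDS = ("uniprot", "refseq", "genbank_protein", "pdb", "genbank_nucleotide")

#: The 20 canonical amino-acid one-letter codes.  Anything else (notably
#: "X") is a nonstandard residue: several prediction tools reject such
#: sequences outright.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class CatalogError(ValueError):
    """Raised for invalid catalog entries or curation conflicts."""


class DesignationParseError(CatalogError):
    """Raised when an allergen designation string cannot be parsed."""


class Completeness(str, enum.Enum):
    COMPLETE = "complete"
    PARTIAL = "partial"
    ABSENT = "absent"


# --------------------------------------------------------------------------
# WHO/IUIS designation parsing
# --------------------------------------------------------------------------

_NUMBER_TOKEN = re.compile(r"^(\d+)(?:\.(\d+))?$")


@dataclass(frozen=True)
class AllergenDesignation:
    """A WHO/IUIS allergen designation split into its components.

    ``allergen_base`` is e.g. ``"Gad m 1"`` (genus abbreviation, species
    abbreviation, allergen number); isoallergens append two digits
    (``Gad m 1.01``) and variants two more (``Gad m 1.0101``).
    """

    allergen_base: str
    isoallergen_code: Optional[str] = None
    variant_code: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variant_code is not None and self.isoallergen_code is None:
            raise CatalogError(
                "variant code requires an isoallergen code: %r" % (self,)
            )
        for code in (self.isoallergen_code, self.variant_code):
            if code is not None and not re.fullmatch(r"\d{2}", code):
                raise CatalogError("iso/variant codes are 2 digits, got %r" % code)

    def __str__(self) -> str:
        if self.isoallergen_code is None:
            return self.allergen_base
        suffix = self.isoallergen_code + (self.variant_code or "")
        return f"{self.allergen_base}.{suffix}"


def parse_allergen_designation(name: str) -> AllergenDesignation:
    """Parse a WHO/IUIS designation like ``"Gad m 1.0101"``.

    Whitespace is collapsed; the genus token is capitalized and the species
    abbreviation (one or two lowercase tokens, e.g. ``"m"`` or ``"sa"``)
    lowercased, so ``"gad  M 1.01"`` normalizes to ``"Gad m 1.01"``.

    Raises
    ------
    DesignationParseError
        If there is no allergen-number token, or the digits after the dot
        are not exactly 2 (isoallergen) or 4 (isoallergen+variant).
    """
    if not name or not name.strip():
        raise DesignationParseError("empty designation")
    tokens = name.split()
    if len(tokens) < 3 or len(tokens) > 4:
        raise DesignationParseError(
            f"expected 'Genus sp[ sp] N[.NN[NN]]', got {name!r}"
        )
    m = _NUMBER_TOKEN.match(tokens[-1])
    if m is None:
        raise DesignationParseError(
            f"no allergen-number token in {name!r} (offending token {tokens[-1]!r})"
        )
    number, digits = m.group(1), m.group(2)
    genus = tokens[0].capitalize()
    species = " ".join(t.lower() for t in tokens[1:-1])
    if not genus.isalpha() or not all(t.isalpha() for t in tokens[1:-1]):
        raise DesignationParseError(f"non-alphabetic name tokens in {name!r}")
    base = f"{genus} {species} {int(number)}"
    if digits is None:
        return AllergenDesignation(base)
    if len(digits) == 2:
        return AllergenDesignation(base, digits)
    if len(digits) == 4:
        return AllergenDesignation(base, digits[:2], digits[2:])
    raise DesignationParseError(
        f"iso/variant suffix must be 2 or 4 digits, got {tokens[-1]!r}"
    )


# --------------------------------------------------------------------------
# Catalog entries
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AllergenEntry:
    """One curated catalog row for an isoallergen or variant."""

    designation: Optional[AllergenDesignation]
    biochemical_name: str
    species_latin: str
    species_common: str = ""
    accessions: Mapping[str, str] = field(default_factory=dict)
    sequence: Optional[str] = None
    completeness: Completeness = Completeness.ABSENT
    source_flags: Mapping[str, bool] = field(default_factory=dict)
    pmids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        acc = {k: v for k, v in dict(self.accessions).items() if v}
        unknown = set(acc) - set(ACCESSION_KINDS)
        if unknown:
            raise CatalogError(f"unknown accession kinds: {sorted(unknown)}")
        object.__setattr__(self, "accessions", acc)
        flags = {db: bool(dict(self.source_flags).get(db, False)) for db in SOURCE_DATABASES}
        object.__setattr__(self, "source_flags", flags)
        if not any(flags.values()):
            raise CatalogError(f"entry {self.label()!r} has no source database flag")
        if self.completeness is Completeness.ABSENT and self.sequence:
            raise CatalogError(
                f"entry {self.label()!r}: completeness 'absent' but sequence present"
            )
        if self.designation is None and not acc:
            raise CatalogError("entry needs a designation or at least one accession")
        if self.sequence is not None:
            object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "pmids", tuple(self.pmids))

    def label(self) -> str:
        if self.designation is not None:
            return str(self.designation)
        return next((self.accessions.get(k) for k in ACCESSION_KINDS if self.accessions.get(k)), "<unkeyed>")

    @property
    def sources(self) -> frozenset[str]:
        return frozenset(db for db, on in self.source_flags.items() if on)


@dataclass(frozen=True)
class ToolOutcome:
    """One prediction-tool verdict for a known allergen.

    ``rejected_nonstandard`` flags sequences a tool could not process (e.g.
    multiple "X" residues); such entries score as not detected.
    """

    entry_key: str
    detected: bool
    rejected_nonstandard: bool = False

    def __post_init__(self) -> None:
        if self.rejected_nonstandard and self.detected:
            raise CatalogError(
                f"{self.entry_key}: a rejected sequence cannot be detected"
            )


def select_primary_accession(entry: AllergenEntry) -> tuple[str, str]:
    """Return the highest-priority (kind, accession) pair for an entry.

    Priority: UniProt > RefSeq > GenBank protein > PDB (> GenBank
    nucleotide as a final fallback).
    """
    for kind in ACCESSION_KINDS:
        acc = entry.accessions.get(kind)
        if acc:
            return kind, acc
    raise CatalogError(f"entry {entry.label()!r} has no accession")


def entry_key(entry: AllergenEntry) -> str:
    """The deduplication key: normalized designation, else primary accession."""
    if entry.designation is not None:
        return str(entry.designation)
    return select_primary_accession(entry)[1]


def _merge_pair(a: AllergenEntry, b: AllergenEntry, key: str) -> AllergenEntry:
    if a.sequence and b.sequence and a.sequence != b.sequence:
        raise CatalogError(
            f"conflicting sequences under key {key!r}: "
            f"{a.label()!r} vs {b.label()!r}"
        )
    accessions = dict(a.accessions)
    for kind, acc in b.accessions.items():
        accessions.setdefault(kind, acc)
    flags = {db: a.source_flags[db] or b.source_flags[db] for db in SOURCE_DATABASES}
    pmids = a.pmids + tuple(p for p in b.pmids if p not in a.pmids)
    order = [Completeness.COMPLETE, Completeness.PARTIAL, Completeness.ABSENT]
    completeness = min((a.completeness, b.completeness), key=order.index)
    return replace(
        a,
        accessions=accessions,
        source_flags=flags,
        pmids=pmids,
        sequence=a.sequence or b.sequence,
        completeness=completeness,
        designation=a.designation or b.designation,
    )


def deduplicate_entries(entries: Sequence[AllergenEntry]) -> list[AllergenEntry]:
    """Collapse rows that describe the same isoallergen/variant.

    Rows are keyed by normalized designation (accession for unassigned
    rows); duplicates — e.g. one variant listed under three different
    sequence IDs — merge their accessions and PMIDs and OR their source
    flags.  Two sources disagreeing on the sequence for one key is a
    curation conflict and raises rather than silently picking one.
    """
    merged: dict[str, AllergenEntry] = {}
    for entry in entries:
        key = entry_key(entry)
        if key in merged:
            merged[key] = _merge_pair(merged[key], entry, key)
        else:
            merged[key] = entry
    return list(merged.values())


def filter_complete(entries: Iterable[AllergenEntry]) -> list[AllergenEntry]:
    """Keep only entries with complete amino-acid sequences (order preserved)."""
    return [e for e in entries if e.completeness is Completeness.COMPLETE]


def database_overlap(entries: Iterable[AllergenEntry]) -> dict[frozenset[str], int]:
    """Count entries per source-database combination (Venn cells).

    The counts over the 15 possible non-empty combinations sum to the number
    of entries; the all-four cell is the "common to every database" count.
    """
    return dict(Counter(e.sources for e in entries))


@dataclass(frozen=True)
class FamilySummary:
    total: int
    iuis_assigned: int
    unassigned: int
    n_species: int


def summarize_families(entries: Iterable[AllergenEntry]) -> dict[str, FamilySummary]:
    """Per biochemical name: totals split by IUIS assignment, and species counts.

    Expects a deduplicated, completeness-filtered catalog; an entry counts as
    IUIS-assigned when it carries a parsed designation.
    """
    rows: dict[str, list[AllergenEntry]] = {}
    for e in entries:
        rows.setdefault(e.biochemical_name, []).append(e)
    out = {}
    for name, group in rows.items():
        assigned = sum(1 for e in group if e.designation is not None)
        out[name] = FamilySummary(
            total=len(group),
            iuis_assigned=assigned,
            unassigned=len(group) - assigned,
            n_species=len({e.species_latin for e in group}),
        )
    return out


def _round_half_up(value: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def compute_sensitivity(outcomes: Sequence[ToolOutcome]) -> float:
    """Percent of known allergens a tool detected, half-up to 1 decimal.

    Every outcome refers to a true allergen, so sensitivity is simply
    ``100 * detected / total``.  Sequences a tool rejected for nonstandard
    residues carry ``detected=False`` by construction and therefore count
    as missed — unprocessable is not a free pass.
    """
    if not outcomes:
        raise CatalogError("cannot compute sensitivity of an empty outcome list")
    detected = sum(1 for o in outcomes if o.detected)
    return _round_half_up(100.0 * detected / len(outcomes), 1)


def has_nonstandard_residues(sequence: str) -> bool:
    """True if any residue falls outside the 20 canonical one-letter codes."""
    return any(ch not in CANONICAL_RESIDUES for ch in sequence.upper())


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

_CATALOG_COLUMNS = [
    "designation",
    "biochemical_name",
    "species_latin",
    "species_common",
    *ACCESSION_KINDS,
    "completeness",
    *[f"in_{db}" for db in SOURCE_DATABASES],
    "pmids",
    "sequence",
]


def read_catalog(path: str | Path) -> list[AllergenEntry]:
    """Read a catalog TSV/CSV (delimiter inferred from the extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    entries = []
    for _, row in df.iterrows():
        desig = (
            parse_allergen_designation(row["designation"])
            if row.get("designation", "")
            else None
        )
        entries.append(
            AllergenEntry(
                designation=desig,
                biochemical_name=row.get("biochemical_name", ""),
                species_latin=row.get("species_latin", ""),
                species_common=row.get("species_common", ""),
                accessions={k: row.get(k, "") for k in ACCESSION_KINDS},
                sequence=row.get("sequence", "") or None,
                completeness=Completeness(row.get("completeness", "absent") or "absent"),
                source_flags={
                    db: row.get(f"in_{db}", "").strip().lower() in {"1", "true", "yes"}
                    for db in SOURCE_DATABASES
                },
                pmids=tuple(p for p in row.get("pmids", "").split(";") if p),
            )
        )
    return entries


def write_catalog(entries: Iterable[AllergenEntry], path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    rows = []
    for e in entries:
        row = {
            "designation": str(e.designation) if e.designation else "",
            "biochemical_name": e.biochemical_name,
            "species_latin": e.species_latin,
            "species_common": e.species_common,
            **{k: e.accessions.get(k, "") for k in ACCESSION_KINDS},
            "completeness": e.completeness.value,
            **{f"in_{db}": int(e.source_flags[db]) for db in SOURCE_DATABASES},
            "pmids": ";".join(e.pmids),
            "sequence": e.sequence or "",
        }
        rows.append(row)
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, sep=sep, index=False)


def entries_to_fasta(entries: Iterable[AllergenEntry], path: str | Path) -> int:
    """Write sequences to FASTA; record ids are entry keys. Returns count written."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(e.sequence), id=entry_key(e).replace(" ", "_"), description="")
        for e in entries
        if e.sequence
    ]
    return seqio_write(records, str(path), "fasta")
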