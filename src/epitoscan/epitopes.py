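"""Linear B-cell epitope filtering and mismatch-tolerant mapping.

IEDB-style exports mix linear and conformational epitopes from positive and
negative assay outcomes.  Only linear epitopes can be mapped onto a bare
amino-acid sequence, so this module (1) filters an export down to a
deduplicated set of linear peptides of one polarity, and (2) scans each
target sequence for ungapped windows matching an epitope within a Hamming
distance budget.  Four per-sequence statistics result: exact positive
matches, positive matches with up to two mismatches, and the negative-assay
counterparts.  Counts are per distinct epitope peptide — an epitope hitting
four windows of one parvalbumin still counts once.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .catalog import CANONICAL_RESIDUES

__all__ = [
    "EpitopeError",
    "Polarity",
    "EpitopeType",
    "EpitopeRecord",
    "EpitopeSet",
    "EpitopeHit",
    "EpitopeCountRow",
    "build_epitope_set",
    "find_matches",
    "count_epitope_hits",
    "annotate_counts",
    "read_epitope_table",
    "write_epitope_table",
    "write_count_table",
    "read_count_table",
]

MIN_EPITOPE_LENGTH = 4


class EpitopeError(ValueError):
    pass


class Polarity(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class EpitopeType(str, enum.Enum):
    LINEAR = "linear"
    CONFORMATIONAL = "conformational"


@dataclass(frozen=True)
class EpitopeRecord:
    """One epitope assay record: a peptide with polarity, type and source."""

    peptide: str
    polarity: Polarity
    epitope_type: EpitopeType
    source_species: str = ""
    assay_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptide", self.peptide.upper())
        if len(self.peptide) < MIN_EPITOPE_LENGTH:
            raise EpitopeError(
                f"epitope peptide shorter than {MIN_EPITOPE_LENGTH}: {self.peptide!r}"
            )
        bad = set(self.peptide) - CANONICAL_RESIDUES
        if bad:
            raise EpitopeError(
                f"peptide {self.peptide!r} contains noncanonical residues {sorted(bad)}"
            )
        object.__setattr__(self, "assay_ids", tuple(self.assay_ids))


@dataclass(frozen=True)
class EpitopeSet:
    """A deduplicated collection of linear epitopes of one polarity."""

    records: tuple[EpitopeRecord, ...]
    polarity: Polarity

    def __post_init__(self) -> None:
        peptides = [r.peptide for r in self.records]
        if len(set(peptides)) != len(peptides):
            raise EpitopeError("duplicate peptides in EpitopeSet")
        for r in self.records:
            if r.epitope_type is not EpitopeType.LINEAR:
                raise EpitopeError(f"non-linear epitope in set: {r.peptide!r}")
            if r.polarity is not self.polarity:
                raise EpitopeError(f"polarity mismatch in set: {r.peptide!r}")

    @property
    def peptides(self) -> tuple[str, ...]:
        return tuple(r.peptide for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class EpitopeHit:
    """One window match of an epitope on a sequence (1-based start)."""

    epitope_peptide: str
    start: int
    mismatches: int


@dataclass(frozen=True)
class EpitopeCountRow:
    """The four epitope-count statistics for one sequence.

    ``n_positive``/``n_negative`` are exact-match counts; the ``_2m``
    variants allow up to two mismatches, so they can only be larger.  The
    two pass-through fields hold externally supplied similarity scores
    (percent identity over an 80-residue linear window and over the 3D
    epitope surface) when available.
    """

    sequence_id: str
    n_positive: int
    n_positive_2m: int
    n_negative: int
    n_negative_2m: int
    passthrough_linear80: Optional[float] = None
    passthrough_3depi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_positive > self.n_positive_2m or self.n_negative > self.n_negative_2m:
            raise EpitopeError(
                f"{self.sequence_id}: mismatch-tolerant count below exact count"
            )
        if min(self.n_positive, self.n_negative) < 0:
            raise EpitopeError(f"{self.sequence_id}: negative count")


def build_epitope_set(
    raw: Iterable[EpitopeRecord],
    polarity: Polarity | str,
    restrict_to: Optional[Callable[[EpitopeRecord], bool] | Iterable[str]] = None,
) -> EpitopeSet:
    """Filter raw records down to a deduplicated linear set of one polarity.

    Conformational records are dropped; records of the other polarity are
    rejected with a warning naming them; ``restrict_to`` optionally keeps
    only records whose source species is in the given collection (or for
    which the given predicate returns True).  Identical peptides collapse
    into one record with merged assay ids.
    """
    polarity = Polarity(polarity)
    if restrict_to is None:
        keep = lambda r: True  # noqa: E731
    elif callable(restrict_to):
        keep = restrict_to
    else:
        wanted = {s.lower() for s in restrict_to}
        keep = lambda r: r.source_species.lower() in wanted  # noqa: E731

    by_peptide: dict[str, EpitopeRecord] = {}
    rejected: list[str] = []
    for rec in raw:
        if rec.polarity is not polarity:
            rejected.append(rec.peptide)
            continue
        if rec.epitope_type is not EpitopeType.LINEAR or not keep(rec):
            continue
        prev = by_peptide.get(rec.peptide)
        if prev is None:
            by_peptide[rec.peptide] = rec
        else:
            merged = prev.assay_ids + tuple(
                a for a in rec.assay_ids if a not in prev.assay_ids
            )
            by_peptide[rec.peptide] = EpitopeRecord(
                prev.peptide, prev.polarity, prev.epitope_type,
                prev.source_species, merged,
            )
    if rejected:
        warnings.warn(
            f"rejected {len(rejected)} record(s) of the wrong polarity: "
            + ", ".join(rejected[:5]),
            stacklevel=2,
        )
    if not by_peptide:
        warnings.warn("epitope set is empty after filtering", stacklevel=2)
    return EpitopeSet(tuple(by_peptide.values()), polarity)


def find_matches(peptide: str, sequence: str, max_mismatches: int) -> list[EpitopeHit]:
    """All ungapped windows where ``peptide`` matches within the mismatch budget.

    Matching is case-insensitive Hamming comparison: substitutions only, no
    indels.  Nonstandard residues (e.g. "X") never match anything, including
    another X — a masked position always spends a mismatch.  Hits are
    returned in ascending start order (1-based).  A sequence shorter than
    the peptide yields no hits.
    """
    if max_mismatches < 0:
        raise EpitopeError("max_mismatches must be >= 0")
    peptide = peptide.upper()
    sequence = sequence.upper()
    L, n = len(peptide), len(sequence)
    if L == 0:
        raise EpitopeError("empty peptide")
    hits: list[EpitopeHit] = []
    for start in range(n - L + 1):
        mm = 0
        for k in range(L):
            p, s = peptide[k], sequence[start + k]
            if p != s or p not in CANONICAL_RESIDUES or s not in CANONICAL_RESIDUES:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            hits.append(EpitopeHit(peptide, start + 1, mm))
    return hits


def count_epitope_hits(
    eset: EpitopeSet, sequence: str, max_mismatches: int
) -> int:
    """Number of distinct epitopes in the set with at least one hit."""
    return sum(
        1 for pep in eset.peptides if find_matches(pep, sequence, max_mismatches)
    )


def annotate_counts(
    sequences: Sequence[tuple[str, str]],
    pos_set: EpitopeSet,
    neg_set: EpitopeSet,
    passthrough: Optional[Mapping[str, tuple[Optional[float], Optional[float]]]] = None,
    max_mismatches: int = 2,
) -> list[EpitopeCountRow]:
    """Compute the four count statistics for each (id, sequence) pair.

    Exact counts use a zero-mismatch scan; the "-2M" counts allow up to
    ``max_mismatches`` (two, by convention).  ``passthrough`` optionally
    maps sequence ids to (linear-80-window %identity, 3D-epitope %identity)
    pairs from an external structural predictor.
    """
    ids = [sid for sid, _ in sequences]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise EpitopeError(f"duplicate sequence ids: {dupes}")
    if pos_set.polarity is not Polarity.POSITIVE or neg_set.polarity is not Polarity.NEGATIVE:
        raise EpitopeError("pos_set/neg_set polarities are swapped")
    rows = []
    for sid, seq in sequences:
        extra = (passthrough or {}).get(sid, (None, None))
        rows.append(
            EpitopeCountRow(
                sequence_id=sid,
                n_positive=count_epitope_hits(pos_set, seq, 0),
                n_positive_2m=count_epitope_hits(pos_set, seq, max_mismatches),
                n_negative=count_epitope_hits(neg_set, seq, 0),
                n_negative_2m=count_epitope_hits(neg_set, seq, max_mismatches),
                passthrough_linear80=extra[0],
                passthrough_3depi=extra[1],
            )
        )
    return rows


# --------------------------------------------------------------------------
# I/O — TSV layouts matching an IEDB-style export's relevant columns
# --------------------------------------------------------------------------

COUNT_COLUMNS = [
    "sequence_id",
    "n_positive",
    "n_positive_2m",
    "n_negative",
    "n_negative_2m",
    "passthrough_linear80",
    "passthrough_3depi",
]


def read_epitope_table(path: str | Path) -> list[EpitopeRecord]:
    """Read a TSV with columns peptide, polarity, type, species, assay_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        records.append(
            EpitopeRecord(
                peptide=row["peptide"],
                polarity=Polarity(row["polarity"]),
                epitope_type=EpitopeType(row["type"]),
                source_species=row.get("species", ""),
                assay_ids=tuple(a for a in row.get("assay_id", "").split(";") if a),
            )
        )
    return records


def write_epitope_table(records: Iterable[EpitopeRecord], path: str | Path) -> None:
    rows = [
        {
            "peptide": r.peptide,
            "polarity": r.polarity.value,
            "type": r.epitope_type.value,
            "species": r.source_species,
            "assay_id": ";".join(r.assay_ids),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["peptide", "polarity", "type", "species", "assay_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_count_table(rows: Iterable[EpitopeCountRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sequence_id": r.sequence_id,
                "n_positive": r.n_positive,
                "n_positive_2m": r.n_positive_2m,
                "n_negative": r.n_negative,
                "n_negative_2m": r.n_negative_2m,
                "passthrough_linear80": r.passthrough_linear80,
                "passthrough_3depi": r.passthrough_3depi,
            }
            for r in rows
        ],
        columns=COUNT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> list[EpitopeCountRow]:
    df = pd.read_csv(path, sep="\t")
    rows = []
    for _, r in df.iterrows():
        rows.append(
            EpitopeCountRow(
                sequence_id=str(r["sequence_id"]),
                n_positive=int(r["n_positive"]),
                n_positive_2m=int(r["n_positive_2m"]),
                n_negative=int(r["n_negative"]),
                n_negative_2m=int(r["n_negative_2m"]),
                passthrough_linear80=None if pd.isna(r.get("passthrough_linear80")) else float(r["passthrough_linear80"]),
                passthrough_3depi=None if pd.isna(r.get("passthrough_3depi")) else float(r["passthrough_3depi"]),
            )
        )
    return rows
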