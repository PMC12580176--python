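"""Synthetic parvalbumin-like panels with planted epitopes and ground truth.

The analysis distinguishes epitope-rich sequences (beta-parvalbumin-like,
highly allergenic) from epitope-poor ones (alpha-parvalbumin-like).  This
generator emulates exactly that structure without any downloaded data: a
random positive-epitope library is planted into "allergenic" sequences with
0-2 substitutions per copy (inside the mapper's mismatch horizon), while
"non-allergenic" sequences receive at most one heavily mutated decoy (3-4
substitutions, beyond the horizon).  Every planted copy is recorded as
ground truth that the mapper must rediscover, so the generator doubles as
an oracle for end-to-end tests.

Defaults mirror the study conditions: panel sizes 11 vs 9 (the parvalbumin
panel's class sizes), 109-residue sequences (a typical parvalbumin length),
and positive/negative library sizes 92 and 83 (the linear epitope counts in
the curated IEDB export).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import CANONICAL_RESIDUES
from .epitopes import (
    EpitopeRecord,
    EpitopeSet,
    EpitopeType,
    Polarity,
    annotate_counts,
    find_matches,
    write_epitope_table,
)
from .thresholding import Label, LabeledCount

__all__ = [
    "SyntheticDataError",
    "SyntheticConfig",
    "TruthRecord",
    "SyntheticDataset",
    "generate_epitope_library",
    "generate_panel",
    "verify_truth",
    "labeled_counts",
    "write_dataset",
]

RESIDUES = np.array(sorted(CANONICAL_RESIDUES))


class SyntheticDataError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults are the intended study conditions."""

    n_allergenic: int = 11
    n_nonallergenic: int = 9
    seq_length: int = 109
    n_pos_epitopes: int = 92
    n_neg_epitopes: int = 83
    epitope_len_range: tuple[int, int] = (8, 20)
    plant_rate_allergenic: float = 6.0
    plant_mismatch_max: int = 2
    min_plant_allergenic: int = 4
    decoy_mismatch_range: tuple[int, int] = (3, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.epitope_len_range
        if min(self.n_allergenic, self.n_nonallergenic, self.seq_length) < 1:
            raise SyntheticDataError("panel sizes and sequence length must be positive")
        if not (4 < lo <= hi < self.seq_length):
            raise SyntheticDataError(
                f"epitope_len_range {self.epitope_len_range} must lie within "
                f"(4, {self.seq_length})"
            )
        if not (0 <= self.plant_mismatch_max <= 2):
            raise SyntheticDataError("plant_mismatch_max must be 0..2 for in-threshold planting")
        if self.decoy_mismatch_range[0] <= self.plant_mismatch_max:
            raise SyntheticDataError("decoy mismatches must exceed plant_mismatch_max")
        if self.min_plant_allergenic < 1:
            raise SyntheticDataError("min_plant_allergenic must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    """One planted epitope copy: where it went and how mutated it is."""

    sequence_id: str
    epitope_peptide: str
    start: int  # 1-based
    injected_mismatches: int


@dataclass(frozen=True)
class SyntheticDataset:
    config: SyntheticConfig
    sequences: tuple[tuple[str, str], ...]
    labels: Mapping[str, Label]
    pos_library: EpitopeSet
    neg_library: EpitopeSet
    truth: tuple[TruthRecord, ...]


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RESIDUES, size=length))


def generate_epitope_library(
    n: int,
    len_range: tuple[int, int],
    seed: int | np.random.Generator,
    polarity: Polarity | str = Polarity.POSITIVE,
) -> EpitopeSet:
    """``n`` distinct random peptides, lengths uniform in ``len_range``."""
    if n < 1:
        raise SyntheticDataError("library size must be >= 1")
    lo, hi = len_range
    capacity = sum(len(RESIDUES) ** L for L in range(lo, hi + 1))
    if n > capacity:
        raise SyntheticDataError(
            f"cannot draw {n} distinct peptides of lengths {lo}..{hi}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    polarity = Polarity(polarity)
    seen: dict[str, None] = {}
    while len(seen) < n:
        length = int(rng.integers(lo, hi + 1))
        seen.setdefault(_random_peptide(rng, length), None)
    records = tuple(
        EpitopeRecord(pep, polarity, EpitopeType.LINEAR, "synthetic", (f"synth:{i}",))
        for i, pep in enumerate(seen)
    )
    return EpitopeSet(records, polarity)


def _mutate(peptide: str, n_subs: int, rng: np.random.Generator) -> str:
    """Substitute exactly ``n_subs`` distinct positions with different residues."""
    if n_subs == 0:
        return peptide
    out = list(peptide)
    positions = rng.choice(len(peptide), size=n_subs, replace=False)
    for pos in positions:
        alternatives = [r for r in RESIDUES if r != out[pos]]
        out[pos] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(out)


def _plant(
    seq: list[str],
    peptides: Sequence[str],
    mismatch_draws: Sequence[int],
    rng: np.random.Generator,
    seq_id: str,
) -> list[TruthRecord]:
    """Write mutated epitope copies into non-overlapping windows of ``seq``.

    Windows are laid out left to right with random non-negative gaps, so
    planted copies replace background residues and never overlap.
    """
    total = sum(len(p) for p in peptides)
    slack = len(seq) - total
    if slack < 0:
        raise SyntheticDataError(
            f"{seq_id}: cannot fit {len(peptides)} epitopes "
            f"({total} residues) into {len(seq)} positions without overlap"
        )
    gaps = rng.multinomial(slack, np.full(len(peptides) + 1, 1.0 / (len(peptides) + 1)))
    truth = []
    cursor = 0
    for pep, gap, m in zip(peptides, gaps, mismatch_draws):
        cursor += int(gap)
        copy = _mutate(pep, m, rng)
        seq[cursor : cursor + len(pep)] = list(copy)
        truth.append(TruthRecord(seq_id, pep, cursor + 1, m))
        cursor += len(pep)
    return truth


def generate_panel(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the two-class panel with planted-epitope ground truth.

    Allergenic sequences receive ``max(min_plant, Poisson(rate))`` distinct
    positive epitopes, truncated to what fits the sequence (never below the
    minimum, which errors instead), each copy carrying Uniform{0..max}
    substitutions.  Non-allergenic sequences receive 0 or 1 decoy copy
    carrying 3-4 substitutions — outside the two-mismatch mapping horizon.
    """
    rng = np.random.default_rng(cfg.seed)
    pos_lib = generate_epitope_library(
        cfg.n_pos_epitopes, cfg.epitope_len_range, rng, Polarity.POSITIVE
    )
    neg_lib = generate_epitope_library(
        cfg.n_neg_epitopes, cfg.epitope_len_range, rng, Polarity.NEGATIVE
    )
    pos_peptides = list(pos_lib.peptides)

    sequences: list[tuple[str, str]] = []
    labels: dict[str, Label] = {}
    truth: list[TruthRecord] = []

    for i in range(cfg.n_allergenic):
        sid = f"allergenic_{i + 1:02d}"
        seq = list(rng.choice(RESIDUES, size=cfg.seq_length))
        k = max(cfg.min_plant_allergenic, int(rng.poisson(cfg.plant_rate_allergenic)))
        k = min(k, len(pos_peptides))
        chosen = [pos_peptides[j] for j in rng.choice(len(pos_peptides), size=k, replace=False)]
        # Truncate to sequence capacity, but never below the configured minimum.
        while len(chosen) > cfg.min_plant_allergenic and sum(map(len, chosen)) > cfg.seq_length:
            chosen.pop()
        draws = [int(rng.integers(0, cfg.plant_mismatch_max + 1)) for _ in chosen]
        truth.extend(_plant(seq, chosen, draws, rng, sid))
        sequences.append((sid, "".join(seq)))
        labels[sid] = Label.ALLERGENIC

    for i in range(cfg.n_nonallergenic):
        sid = f"nonallergenic_{i + 1:02d}"
        seq = list(rng.choice(RESIDUES, size=cfg.seq_length))
        if rng.integers(0, 2):
            pep = pos_peptides[int(rng.integers(0, len(pos_peptides)))]
            m = int(rng.integers(cfg.decoy_mismatch_range[0], cfg.decoy_mismatch_range[1] + 1))
            truth.extend(_plant(seq, [pep], [m], rng, sid))
        sequences.append((sid, "".join(seq)))
        labels[sid] = Label.LESS_NON_ALLERGENIC

    return SyntheticDataset(
        config=cfg,
        sequences=tuple(sequences),
        labels=labels,
        pos_library=pos_lib,
        neg_library=neg_lib,
        truth=tuple(truth),
    )


def verify_truth(ds: SyntheticDataset) -> list[str]:
    """Check every planted copy is rediscovered by the mapper at its own m.

    Returns a list of violation messages; an intact dataset yields an empty
    list.
    """
    seqs = dict(ds.sequences)
    violations = []
    for rec in ds.truth:
        seq = seqs.get(rec.sequence_id)
        if seq is None:
            violations.append(f"{rec.sequence_id}: sequence missing")
            continue
        hits = find_matches(rec.epitope_peptide, seq, rec.injected_mismatches)
        if not any(h.start == rec.start for h in hits):
            violations.append(
                f"{rec.sequence_id}: {rec.epitope_peptide} not found at "
                f"{rec.start} within {rec.injected_mismatches} mismatches"
            )
    return violations


def labeled_counts(ds: SyntheticDataset, max_mismatches: int = 2) -> list[LabeledCount]:
    """Run the mapper on the panel and pair counts with the true labels."""
    rows = annotate_counts(list(ds.sequences), ds.pos_library, ds.neg_library,
                           max_mismatches=max_mismatches)
    return [
        LabeledCount(r.sequence_id, r.n_positive_2m, ds.labels[r.sequence_id])
        for r in rows
    ]


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, epitope TSVs, labels TSV and truth TSV under ``outdir``."""
    import pandas as pd
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "pos": outdir / "epitopes_positive.tsv",
        "neg": outdir / "epitopes_negative.tsv",
        "labels": outdir / "labels.tsv",
        "truth": outdir / "truth.tsv",
    }
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in ds.sequences]
    seqio_write(records, str(paths["fasta"]), "fasta")
    write_epitope_table(ds.pos_library.records, paths["pos"])
    write_epitope_table(ds.neg_library.records, paths["neg"])
    pd.DataFrame(
        [{"sequence_id": sid, "label": label.value} for sid, label in ds.labels.items()]
    ).to_csv(paths["labels"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sequence_id": t.sequence_id,
                "epitope_peptide": t.epitope_peptide,
                "start": t.start,
                "injected_mismatches": t.injected_mismatches,
            }
            for t in ds.truth
        ]
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
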