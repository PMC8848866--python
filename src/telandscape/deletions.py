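"""Species-specific deletions in three-way ortholog blocks and DNA-loss rates.

Blocks are ~10 kb orthologous alignments of an outgroup and two ingroup
species. A maximal gap run in one ingroup row is a species-specific
deletion when the other ingroup and the outgroup are each >= 90% non-gap
over those columns and no gap run of the other ingroup overlaps it.
Deletions are classed micro (< 30 nt), mid-size (30–10,000 nt inclusive)
or excluded (> 10,000 nt, counted separately). The loss rate is the
normalised deleted-nucleotide count per 10 kb of aligned sequence divided
by the My since divergence (del_nt/10 kb/My).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

MICRO_MAX = 29  # nt; micro-deletion upper bound (inclusive)
MID_MAX = 10_000  # nt; mid-size upper bound (inclusive)
WITNESS_NONGAP_FRACTION = 0.9


@dataclass
class OrthologBlock:
    """Equal-length aligned rows: outgroup plus ingroup species A and B."""

    block_id: str
    outgroup: str
    species_a: str
    species_b: str
    names: tuple[str, str, str] = ("outgroup", "A", "B")

    def __post_init__(self) -> None:
        if not (len(self.outgroup) == len(self.species_a) == len(self.species_b)):
            raise ValueError(f"block {self.block_id}: rows of unequal length")

    @property
    def n_columns(self) -> int:
        return len(self.outgroup)


@dataclass(frozen=True)
class DeletionEvent:
    block_id: str
    species: str  # "A" | "B"
    start: int  # column, 0-based
    end: int  # exclusive
    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def size_class(self) -> str:
        if self.length <= MICRO_MAX:
            return "micro"
        if self.length <= MID_MAX:
            return "mid"
        return "excluded"


@dataclass
class LossRates:
    divergence_my: float
    aligned_bp: int
    #: species -> size class -> deleted nt
    del_nt: dict = field(default_factory=dict)

    def del_nt_per_10kb(self, species: str, size_class: str | None = None) -> float:
        classes = ("micro", "mid") if size_class is None else (size_class,)
        nt = sum(self.del_nt.get(species, {}).get(c, 0) for c in classes)
        return nt / self.aligned_bp * 10_000.0

    def rate_per_my(self, species: str, size_class: str | None = None) -> float:
        return self.del_nt_per_10kb(species, size_class) / self.divergence_my

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp in sorted(self.del_nt):
            for cls in ("micro", "mid", "excluded"):
                rows.append(
                    {
                        "species": sp,
                        "size_class": cls,
                        "del_nt": self.del_nt[sp].get(cls, 0),
                        "del_nt_per_10kb": (
                            self.del_nt[sp].get(cls, 0) / self.aligned_bp * 10_000.0
                        ),
                        "rate_per_my": (
                            self.del_nt[sp].get(cls, 0)
                            / self.aligned_bp
                            * 10_000.0
                            / self.divergence_my
                            if cls != "excluded"
                            else float("nan")
                        ),
                    }
                )
        return pd.DataFrame(rows)


def _gap_runs(row: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, c in enumerate(row):
        if c == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(row)))
    return runs


def _nongap_fraction(row: str, start: int, end: int) -> float:
    seg = row[start:end]
    return 1.0 - seg.count("-") / len(seg)


def species_specific_gaps(block: OrthologBlock) -> list[DeletionEvent]:
    """Maximal species-specific gap runs in the two ingroup rows.

    A run qualifies only when the outgroup and the other ingroup are each
    >= 90% non-gap over its columns, and it does not overlap any gap run of
    the other ingroup (shared gaps are not species-specific).
    """
    runs_a = _gap_runs(block.species_a)
    runs_b = _gap_runs(block.species_b)
    events = []
    for species, runs, other_runs, witness in (
        ("A", runs_a, runs_b, block.species_b),
        ("B", runs_b, runs_a, block.species_a),
    ):
        for s, e in runs:
            if any(os < e and s < oe for os, oe in other_runs):
                continue
            if _nongap_fraction(block.outgroup, s, e) < WITNESS_NONGAP_FRACTION:
                continue
            if _nongap_fraction(witness, s, e) < WITNESS_NONGAP_FRACTION:
                continue
            events.append(DeletionEvent(block.block_id, species, s, e))
    return events


def classify_and_rate(
    events: list[DeletionEvent],
    blocks: list[OrthologBlock],
    divergence_my: float,
) -> LossRates:
    """Aggregate events into per-species, per-size-class DNA-loss rates.

    The normalisation base is the total aligned length over all blocks;
    the overall per-species rate uses micro + mid nucleotides (deletions
    above 10 kb are tallied under "excluded" and not rated).
    """
    if divergence_my <= 0:
        raise ValueError("divergence must be positive")
    if not blocks:
        raise ValueError("need at least one block")
    aligned_bp = sum(b.n_columns for b in blocks)
    del_nt: dict[str, dict[str, int]] = {"A": {}, "B": {}}
    for ev in events:
        d = del_nt.setdefault(ev.species, {})
        d[ev.size_class] = d.get(ev.size_class, 0) + ev.length
    return LossRates(divergence_my, aligned_bp, del_nt)


def read_ortholog_blocks(paths: list[str | Path]) -> list[OrthologBlock]:
    """Read one aligned multi-FASTA per block; the first record is the
    outgroup, the next two the ingroup species."""
    blocks = []
    for path in paths:
        recs = list(SeqIO.parse(str(path), "fasta"))
        if len(recs) < 3:
            raise ValueError(f"{path}: need >= 3 aligned rows")
        blocks.append(
            OrthologBlock(
                block_id=Path(path).stem,
                outgroup=str(recs[0].seq).upper(),
                species_a=str(recs[1].seq).upper(),
                species_b=str(recs[2].seq).upper(),
                names=(recs[0].id, recs[1].id, recs[2].id),
            )
        )
    return blocks
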