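"""Genomic compartments (exon / intron / flank / intergenic) and TE occupancy.

Each chromosome is tiled exactly by labelled, disjoint intervals. Where
labels conflict the priority is exon > intron > flank > intergenic: a
position inside one gene's body and another gene's flank is genic, and
overlapping flanks of adjacent genes merge. Flanks extend ``flank_width``
bp (default 20 kb, the proximate-promoter scale) either side of each gene
body, truncated at chromosome ends and neighbouring gene bodies.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import pandas as pd

from .annotation_io import GeneModel, TEAnnotation

COMPARTMENTS = ("exon", "intron", "flank", "intergenic")

Interval = tuple[int, int]


def merge_intervals(ivs: list[Interval]) -> list[Interval]:
    """Union of possibly overlapping intervals, sorted and merged."""
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(base: list[Interval], minus: list[Interval]) -> list[Interval]:
    """Set difference base \\ minus; both inputs merged/sorted internally."""
    base = merge_intervals(base)
    minus = merge_intervals(minus)
    out: list[Interval] = []
    j = 0
    for s, e in base:
        cur = s
        while j < len(minus) and minus[j][1] <= cur:
            j += 1
        k = j
        while k < len(minus) and minus[k][0] < e:
            ms, me = minus[k]
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_length(ivs: list[Interval]) -> int:
    return sum(e - s for s, e in ivs)


@dataclass
class CompartmentMap:
    """Disjoint labelled tiling of each chromosome."""

    chrom_sizes: dict[str, int]
    flank_width: int = 20000
    #: chrom -> label -> sorted disjoint intervals
    intervals: dict[str, dict[str, list[Interval]]] = field(default_factory=dict)

    def label_lengths(self, chrom: str) -> dict[str, int]:
        return {lab: total_length(ivs) for lab, ivs in self.intervals[chrom].items()}

    def genome_label_lengths(self) -> dict[str, int]:
        out = {lab: 0 for lab in COMPARTMENTS}
        for chrom in self.intervals:
            for lab, n in self.label_lengths(chrom).items():
                out[lab] += n
        return out

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                rows = []
                for lab, ivs in self.intervals[chrom].items():
                    rows += [(s, e, lab) for s, e in ivs]
                for s, e, lab in sorted(rows):
                    fh.write(f"{chrom}\t{s}\t{e}\t{lab}\n")


def build_compartments(
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    flank_width: int = 20000,
) -> CompartmentMap:
    """Partition every chromosome into exon/intron/flank/intergenic intervals."""
    cmap = CompartmentMap(dict(chrom_sizes), flank_width)
    by_chrom: dict[str, list[GeneModel]] = {c: [] for c in chrom_sizes}
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        if g.start < 0 or g.end > chrom_sizes[g.chrom]:
            raise ValueError(f"gene {g.gene_id} outside chromosome bounds")
        by_chrom[g.chrom].append(g)
    for chrom, size in chrom_sizes.items():
        exons = merge_intervals([iv for g in by_chrom[chrom] for iv in g.exons])
        bodies = merge_intervals([(g.start, g.end) for g in by_chrom[chrom]])
        introns = subtract_intervals(bodies, exons)
        raw_flanks = [
            (max(0, g.start - flank_width), min(size, g.end + flank_width))
            for g in by_chrom[chrom]
        ]
        flanks = subtract_intervals(raw_flanks, bodies)
        covered = merge_intervals(exons + introns + flanks)
        intergenic = subtract_intervals([(0, size)], covered)
        cmap.intervals[chrom] = {
            "exon": exons,
            "intron": introns,
            "flank": flanks,
            "intergenic": intergenic,
        }
    return cmap


def _overlap_bp(ivs: list[Interval], start: int, end: int) -> int:
    """Total bp of [start, end) intersecting a sorted disjoint interval list."""
    bp = 0
    # first interval whose end exceeds start
    lo = bisect_right([e for _, e in ivs], start)
    for s, e in ivs[lo:]:
        if s >= end:
            break
        bp += min(e, end) - max(s, start)
    return bp


def te_compartment_overlap(
    annots: list[TEAnnotation], cmap: CompartmentMap
) -> pd.DataFrame:
    """TE occupancy per (te_class, compartment): bp and percent of compartment.

    A TE spanning a compartment boundary contributes its bp to every
    compartment it intersects, so per-class bp sums over compartments equal
    the total annotated bp of the class.
    """
    bp: dict[tuple[str, str], int] = {}
    for a in annots:
        if a.chrom not in cmap.intervals:
            raise ValueError(f"annotation on unknown chromosome {a.chrom}")
        if a.end > cmap.chrom_sizes[a.chrom]:
            raise ValueError(
                f"annotation {a.chrom}:{a.start}-{a.end} beyond chromosome end"
            )
        for lab, ivs in cmap.intervals[a.chrom].items():
            n = _overlap_bp(ivs, a.start, a.end)
            if n:
                bp[(a.te_class, lab)] = bp.get((a.te_class, lab), 0) + n
    comp_sizes = cmap.genome_label_lengths()
    classes = sorted({a.te_class for a in annots})
    rows = []
    for klass in classes:
        for lab in COMPARTMENTS:
            n = bp.get((klass, lab), 0)
            rows.append(
                {
                    "te_class": klass,
                    "compartment": lab,
                    "bp": n,
                    "percent_of_compartment": (
                        n / comp_sizes[lab] * 100.0 if comp_sizes[lab] else 0.0
                    ),
                }
            )
    return pd.DataFrame(rows)
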