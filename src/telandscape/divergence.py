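"""Kimura 2-parameter divergence, insertion ages and repeat landscapes.

Each genomic TE copy is compared with its family consensus. Transitions
(A<->G, C<->T) and transversions are counted over gap-free columns, corrected
with the Kimura 2-parameter formula

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

and converted to an insertion age with a neutral substitution rate mu
(default 0.0116 substitutions/site/My). No CpG masking or correction is
applied anywhere: every gap-free column counts. The age divisor defaults to
1 (T = K / mu): divergence from the ancestral consensus accrues on the copy
lineage alone. A divisor of 2 halves all ages and is available for
comparison with pairwise-distance conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np

from .annotation_io import ConsensusLibrary, TEAnnotation

DEFAULT_NEUTRAL_RATE = 0.0116  # substitutions/site/My

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturatedDistanceError(ValueError):
    """K2P correction undefined: 1-2P-Q <= 0 or 1-2Q <= 0."""


class UndefinedDistanceError(ValueError):
    """No gap-free aligned columns to count over."""


@dataclass(frozen=True)
class SubstitutionCounts:
    """Transition/transversion counts over the gap-free columns of a pair."""

    aligned_sites: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.aligned_sites

    @property
    def Q(self) -> float:
        return self.transversions / self.aligned_sites


@dataclass(frozen=True)
class AgeEstimate:
    K: float
    mu: float = DEFAULT_NEUTRAL_RATE
    age_my: float = 0.0


def count_substitutions(copy_row: str, consensus_row: str) -> SubstitutionCounts:
    """Count transitions and transversions between two aligned rows.

    Columns containing a gap (``-``) or ``N`` in either row are excluded
    from the aligned-site total.
    """
    if len(copy_row) != len(consensus_row):
        raise ValueError("aligned rows must have equal length")
    sites = ts = tv = 0
    for a, b in zip(copy_row.upper(), consensus_row.upper()):
        if a in "-N" or b in "-N":
            continue
        sites += 1
        if a != b:
            if (a, b) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if sites == 0:
        raise UndefinedDistanceError("no gap-free columns")
    return SubstitutionCounts(sites, ts, tv)


def kimura2p(P: float, Q: float) -> float:
    """Kimura 2-parameter distance from transition (P) and transversion (Q)
    proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedDistanceError(f"saturated: P={P}, Q={Q}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def age_from_distance(
    K: float, mu: float = DEFAULT_NEUTRAL_RATE, divisor: float = 1.0
) -> float:
    """Insertion age in My: T = K / (divisor * mu)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if K < 0:
        raise ValueError("negative distance")
    return K / (divisor * mu)


def align_to_consensus(copy_seq: str, consensus: str) -> tuple[str, str]:
    """Globally align a (possibly truncated) copy to its consensus with free
    end gaps on the consensus, returning (copy_row, consensus_row).

    Infix alignment fits terminal-truncated fragments without penalising the
    missing consensus ends. Edit-distance alignments trade mismatch runs for
    indel pairs, which deflates substitution counts at high divergence; use
    :func:`locate_ungapped` for colinear fragments.
    """
    res = edlib.align(copy_seq.upper(), consensus.upper(), mode="HW", task="path")
    rows = edlib.getNiceAlignment(res, copy_seq.upper(), consensus.upper())
    return rows["query_aligned"], rows["target_aligned"]


def locate_ungapped(
    copy_seq: str, consensus: str, slack: int = 8
) -> tuple[str, str]:
    """Locate a colinear fragment on its consensus and return the ungapped
    (copy_row, consensus_row) pair.

    The fragment is anchored with an infix edit-distance search, then the
    exact offset is refined by scanning ``slack`` bp either side of the
    anchor for the minimum-mismatch position. For fragments without internal
    indels this recovers the true positional comparison, so transition and
    transversion counts are unbiased even at high divergence.
    """
    frag = copy_seq.upper()
    cons = consensus.upper()
    res = edlib.align(frag, cons, mode="HW", task="locations")
    anchor = res["locations"][0][0]
    fa = np.frombuffer(frag.encode(), dtype=np.uint8)
    ca = np.frombuffer(cons.encode(), dtype=np.uint8)
    best_off, best_mm = None, None
    for off in range(max(0, anchor - slack), min(len(cons) - len(frag), anchor + slack) + 1):
        mm = int((fa != ca[off : off + len(frag)]).sum())
        if best_mm is None or mm < best_mm:
            best_off, best_mm = off, mm
    if best_off is None:
        best_off = max(0, min(anchor, len(cons) - len(frag)))
    return frag, cons[best_off : best_off + len(frag)]


def date_annotation(
    ann: TEAnnotation,
    copy_seq: str,
    library: ConsensusLibrary,
    mu: float = DEFAULT_NEUTRAL_RATE,
    divisor: float = 1.0,
    alignment: str = "ungapped",
) -> TEAnnotation:
    """Attach K2P divergence and age to one annotation (mutates and returns it).

    ``alignment`` selects the copy-to-consensus comparison: "ungapped"
    (default; colinear fragments, unbiased counts) or "gapped" (edit-distance
    path, for fragments carrying internal indels). Saturated copies get
    ``divergence=None`` and are excluded from age summaries downstream.
    """
    consensus = library[ann.family_name]
    if alignment == "ungapped":
        copy_row, cons_row = locate_ungapped(copy_seq, consensus)
    elif alignment == "gapped":
        copy_row, cons_row = align_to_consensus(copy_seq, consensus)
    else:
        raise ValueError(f"unknown alignment mode {alignment!r}")
    counts = count_substitutions(copy_row, cons_row)
    try:
        ann.divergence = kimura2p(counts.P, counts.Q)
        ann.age_my = age_from_distance(ann.divergence, mu, divisor)
    except SaturatedDistanceError:
        ann.divergence = None
        ann.age_my = None
    return ann


def date_annotations(
    annots: list[TEAnnotation],
    genome: dict[str, str],
    library: ConsensusLibrary,
    mu: float = DEFAULT_NEUTRAL_RATE,
    divisor: float = 1.0,
    alignment: str = "ungapped",
) -> list[TEAnnotation]:
    """Date every annotation against its family consensus using the genome
    sequence. Annotations whose family is missing from the library are left
    undated."""
    for ann in annots:
        if ann.family_name not in library:
            continue
        seq = genome[ann.chrom][ann.start : ann.end]
        date_annotation(ann, seq, library, mu, divisor, alignment)
    return annots


def weighted_family_age(ages: list[float], counts: list[int] | None = None) -> float:
    """Copy-number-weighted mean family age in My.

    With ``counts`` given, each age is weighted by its copy count (ages per
    divergence value); otherwise a plain mean over dated copies.
    """
    if not ages:
        raise ValueError("no dated copies")
    a = np.asarray(ages, dtype=float)
    if counts is None:
        return float(a.mean())
    w = np.asarray(counts, dtype=float)
    return float(np.average(a, weights=w))


def family_age_table(annots: list[TEAnnotation]):
    """Per-family weighted age and copy number (Table-2-style summary)."""
    import pandas as pd

    rows = []
    by_family: dict[str, list[TEAnnotation]] = {}
    for a in annots:
        by_family.setdefault(a.family_name, []).append(a)
    for family, group in sorted(by_family.items()):
        dated = [g.age_my for g in group if g.age_my is not None]
        rows.append(
            {
                "family": family,
                "te_class": group[0].te_class,
                "te_subfamily": group[0].te_subfamily,
                "copy_number": len(group),
                "n_dated": len(dated),
                "weighted_age_my": weighted_family_age(dated) if dated else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def repeat_landscape(
    annots: list[TEAnnotation],
    genome_size: int,
    bin_width_pct: float = 1.0,
    max_pct: float = 50.0,
):
    """Genome percent occupied per (te_class, K2P percent bin).

    Copies are binned by K2P distance in percent, 1% bins over [0, 50) by
    default; each copy contributes its genomic length. Undated (saturated)
    copies are skipped.
    """
    import pandas as pd

    n_bins = int(round(max_pct / bin_width_pct))
    classes = sorted({a.te_class for a in annots}) or []
    table = {c: np.zeros(n_bins) for c in classes}
    for a in annots:
        if a.divergence is None:
            continue
        k_pct = a.divergence * 100.0
        if k_pct >= max_pct:
            continue
        b = int(k_pct // bin_width_pct)
        table[a.te_class][b] += a.length
    rows = []
    for c in classes:
        for b in range(n_bins):
            rows.append(
                {
                    "te_class": c,
                    "bin_low_pct": b * bin_width_pct,
                    "bin_high_pct": (b + 1) * bin_width_pct,
                    "genome_percent": table[c][b] / genome_size * 100.0,
                }
            )
    return pd.DataFrame(rows)
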