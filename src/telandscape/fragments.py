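"""LINE/PLE fragment mapping, truncation classification and turnover summaries.

Each genomic fragment is matched to its family consensus; match coordinates
are normalised by consensus length, and the fragment is classed by which
consensus ends it reaches (within ``end_tolerance_bp``, default 20 bp):

- ``five_prime_type``: reaches the 5' end only => 3'-truncated => the
  signature of a genomic deletion removing the element's 3' portion;
- ``three_prime_type``: reaches the 3' end only => 5'-truncated => the
  signature of premature reverse-transcriptase dissociation or RNase decay
  during mobilisation;
- ``full`` / ``internal``: reaches both or neither end; reported separately
  and excluded from the two-class turnover proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import edlib
import pandas as pd

from .annotation_io import ConsensusLibrary

TRUNCATION_CLASSES = ("full", "five_prime_type", "three_prime_type", "internal")

MIN_MAP_IDENTITY = 60.0  # percent; below this a fragment is unmapped
MIN_FRAGMENT_BP = 30


class UnmappedFragmentError(ValueError):
    """No consensus hit at or above the identity floor."""


@dataclass(frozen=True)
class FragmentHit:
    """Best match of one fragment to a family consensus."""

    fragment_id: str
    family_name: str
    percent_identity: float
    consensus_start: int  # 0-based on the consensus
    consensus_end: int  # exclusive
    consensus_length: int
    fragment_length: int

    @property
    def norm_start(self) -> float:
        return self.consensus_start / self.consensus_length

    @property
    def norm_end(self) -> float:
        return self.consensus_end / self.consensus_length

    @property
    def alignment_length(self) -> int:
        return self.consensus_end - self.consensus_start


def _edlib_hit(fragment: str, family: str, consensus: str, frag_id: str) -> FragmentHit | None:
    res = edlib.align(fragment.upper(), consensus.upper(), mode="HW", task="locations")
    if res["editDistance"] < 0:
        return None
    start, end_inc = res["locations"][0]
    aln_len = max(end_inc + 1 - start, len(fragment))
    identity = (1.0 - res["editDistance"] / aln_len) * 100.0
    return FragmentHit(
        fragment_id=frag_id,
        family_name=family,
        percent_identity=identity,
        consensus_start=start,
        consensus_end=end_inc + 1,
        consensus_length=len(consensus),
        fragment_length=len(fragment),
    )


def best_hit(
    fragment: str,
    library: ConsensusLibrary,
    fragment_id: str = "fragment",
    min_identity: float = MIN_MAP_IDENTITY,
) -> FragmentHit:
    """Best consensus match for one fragment across the whole library.

    The top hit is the one with maximal percent identity; ties go to the
    longer alignment, then the lexicographically smaller family name.
    Raises :class:`UnmappedFragmentError` below the identity floor.
    """
    if len(fragment) < MIN_FRAGMENT_BP:
        raise ValueError(f"fragment shorter than {MIN_FRAGMENT_BP} bp")
    best: FragmentHit | None = None
    for family in sorted(library.entries):
        hit = _edlib_hit(fragment, family, library[family], fragment_id)
        if hit is None:
            continue
        if best is None or _hit_key(hit) > _hit_key(best):
            best = hit
    if best is None or best.percent_identity < min_identity:
        raise UnmappedFragmentError(f"no hit >= {min_identity}% identity")
    return best


class _hit_key:
    """Ordering for best-hit selection: higher identity, then longer
    alignment, then lexicographically smaller family name."""

    def __init__(self, h: FragmentHit):
        self.h = h

    def __gt__(self, other: "_hit_key") -> bool:
        a, b = self.h, other.h
        if a.percent_identity != b.percent_identity:
            return a.percent_identity > b.percent_identity
        if a.alignment_length != b.alignment_length:
            return a.alignment_length > b.alignment_length
        return a.family_name < b.family_name


def read_blast_hits(path: str | Path, library: ConsensusLibrary) -> list[FragmentHit]:
    """Load precomputed fragment-vs-consensus hits from 12-column BLAST
    tabular output (qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore), keeping the top hit per fragment by the
    same identity/length/name ordering as :func:`best_hit`."""
    best: dict[str, FragmentHit] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qid, sid = f[0], f[1]
            family = sid.partition("#")[0]
            if family not in library:
                continue
            pident, length = float(f[2]), int(f[3])
            sstart, send = int(f[8]), int(f[9])
            lo, hi = (sstart, send) if sstart <= send else (send, sstart)
            hit = FragmentHit(
                fragment_id=qid,
                family_name=family,
                percent_identity=pident,
                consensus_start=lo - 1,
                consensus_end=hi,
                consensus_length=len(library[family]),
                fragment_length=int(f[7]) - int(f[6]) + 1,
            )
            if qid not in best or _hit_key(hit) > _hit_key(best[qid]):
                best[qid] = hit
    return list(best.values())


def classify_truncation(hit: FragmentHit, end_tolerance_bp: int = 20) -> str:
    """Classify a hit by which consensus ends it reaches (absolute bp
    tolerance at each end)."""
    reaches_5p = hit.consensus_start <= end_tolerance_bp
    reaches_3p = hit.consensus_length - hit.consensus_end <= end_tolerance_bp
    if reaches_5p and reaches_3p:
        return "full"
    if reaches_5p:
        return "five_prime_type"
    if reaches_3p:
        return "three_prime_type"
    return "internal"


def turnover_summary(
    hits: list[FragmentHit],
    classes: list[str] | None = None,
    grouping: dict[str, str] | None = None,
    end_tolerance_bp: int = 20,
) -> dict:
    """Per-group truncation counts/proportions and the overall 3'-truncated
    percentage (Table-3-style).

    ``grouping`` maps family name -> group label (defaults to the family
    itself). Proportions are over the two truncated classes only; full and
    internal fragments are counted separately. The overall percent
    3'-truncated is 100 * sum(five_prime_type) / sum(both truncated classes)
    — five_prime_type fragments retain only the consensus 5' end and are
    therefore truncated at the 3' end.
    """
    if not hits:
        raise ValueError("no classified hits")
    if classes is None:
        classes = [classify_truncation(h, end_tolerance_bp) for h in hits]
    rows = []
    for h, c in zip(hits, classes):
        group = grouping.get(h.family_name, h.family_name) if grouping else h.family_name
        rows.append(
            {"group": group, "class": c, "fragment_length": h.fragment_length}
        )
    df = pd.DataFrame(rows)
    per_group = []
    for group, sub in df.groupby("group", sort=True):
        n5 = int((sub["class"] == "five_prime_type").sum())
        n3 = int((sub["class"] == "three_prime_type").sum())
        trunc = n5 + n3
        per_group.append(
            {
                "group": group,
                "five_prime_type": n5,
                "three_prime_type": n3,
                "full": int((sub["class"] == "full").sum()),
                "internal": int((sub["class"] == "internal").sum()),
                "prop_five_prime": n5 / trunc if trunc else float("nan"),
                "prop_three_prime": n3 / trunc if trunc else float("nan"),
            }
        )
    n5_all = int((df["class"] == "five_prime_type").sum())
    n3_all = int((df["class"] == "three_prime_type").sum())
    total_trunc = n5_all + n3_all
    return {
        "per_group": pd.DataFrame(per_group),
        "n_fragments": len(df),
        "mean_fragment_length": float(df["fragment_length"].mean()),
        "percent_3prime_truncated": (
            100.0 * n5_all / total_trunc if total_trunc else float("nan")
        ),
    }


def hits_to_table(hits: list[FragmentHit], classes: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment\tfamily\tclass\tnorm_start\tnorm_end\tpercent_identity\n")
        for h, c in zip(hits, classes):
            fh.write(
                f"{h.fragment_id}\t{h.family_name}\t{c}\t{h.norm_start:.4f}\t"
                f"{h.norm_end:.4f}\t{h.percent_identity:.2f}\n"
            )
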