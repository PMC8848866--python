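"""Reading, writing and filtering of TE annotations, consensus libraries and gene models.

All in-memory coordinates are 0-based half-open. GFF3 (1-based inclusive) is
converted at the read/write boundary; BED is used as-is. TE classification
strings follow the RepeatMasker convention ``family#Class/Subclass``
(e.g. ``tc1-1_dPle#DNA/TcMar-Tc1``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: canonical TE classes, as used in RepeatMasker-style repeat summaries
TE_CLASSES = (
    "DNA",
    "Rolling-circle",
    "LINE",
    "SINE",
    "PLE",
    "LTR",
    "Unclassified",
    "Other",
)

# maps the leading token of the '#Class/Subclass' suffix to a canonical class
_CLASS_ALIASES = {
    "dna": "DNA",
    "rc": "Rolling-circle",
    "rolling-circle": "Rolling-circle",
    "helitron": "Rolling-circle",
    "line": "LINE",
    "sine": "SINE",
    "ple": "PLE",
    "penelope": "PLE",
    "ltr": "LTR",
    "unknown": "Unclassified",
    "unclassified": "Unclassified",
}


class AnnotationError(ValueError):
    """Malformed annotation record (carries the offending line number)."""


def parse_classification(name: str) -> tuple[str, str, str]:
    """Split a RepeatMasker-style name into (family, te_class, te_subfamily).

    ``tc1-1_dPle#DNA/TcMar-Tc1`` -> ("tc1-1_dPle", "DNA", "TcMar-Tc1").
    A name without a recognisable ``#Class`` suffix maps to Unclassified.
    ``LINE/Penelope`` is treated as PLE, matching the repeat-summary
    convention of reporting Penelope-like elements as their own class.
    """
    family, _, classif = name.partition("#")
    if not classif:
        return name, "Unclassified", ""
    head, _, sub = classif.partition("/")
    if head.lower() == "line" and sub.lower().startswith("penelope"):
        return family, "PLE", sub
    te_class = _CLASS_ALIASES.get(head.lower())
    if te_class is None:
        te_class = "Other" if head else "Unclassified"
    return family, te_class, sub


@dataclass
class TEAnnotation:
    """One genomic TE interval with its family classification and mask score."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "."
    family_name: str = ""
    te_class: str = "Unclassified"
    te_subfamily: str = ""
    score: float = 0.0
    divergence: float | None = None  # K2P, substitutions/site
    age_my: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def full_name(self) -> str:
        if self.te_subfamily:
            return f"{self.family_name}#{self.te_class}/{self.te_subfamily}"
        if self.te_class != "Unclassified" or "#" in self.family_name:
            return f"{self.family_name}#{self.te_class}"
        return self.family_name


@dataclass
class ConsensusLibrary:
    """A TE family consensus library: family name -> consensus sequence."""

    entries: dict[str, str] = field(default_factory=dict)
    te_class: dict[str, str] = field(default_factory=dict)
    te_subfamily: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, sequence: str) -> None:
        family, klass, sub = parse_classification(name)
        if family in self.entries:
            raise ValueError(f"duplicate family name {family!r}")
        seq = sequence.upper()
        if not seq or set(seq) - set("ACGTN"):
            raise ValueError(f"bad alphabet in consensus {family!r}")
        self.entries[family] = seq
        self.te_class[family] = klass
        self.te_subfamily[family] = sub

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, family: str) -> bool:
        return family in self.entries

    def __getitem__(self, family: str) -> str:
        return self.entries[family]


@dataclass
class GeneModel:
    """A gene span with its exon structure and free-text gene-set labels."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    gene_set_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(f"empty gene span for {self.gene_id}")
        self.exons = sorted(self.exons)
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise AnnotationError(
                    f"exon ({s},{e}) of {self.gene_id} overlaps or exceeds the span"
                )
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# readers / writers


def read_te_annotations(path: str | Path, dialect: str = "bed") -> list[TEAnnotation]:
    """Read TE annotations from BED6 or GFF3, parsing the class suffix.

    BED records are 0-based half-open; GFF3 records 1-based inclusive and
    are converted on read. Record order is preserved. Malformed coordinates
    raise :class:`AnnotationError` naming the line.
    """
    if dialect not in ("bed", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r} (expected 'bed' or 'gff3')")
    out: list[TEAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else ""
                    score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                    strand = fields[5] if len(fields) > 5 else "."
                    attrs: dict[str, str] = {}
                else:
                    chrom = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    score = float(fields[5]) if fields[5] != "." else 0.0
                    strand = fields[6] if fields[6] in "+-" else "."
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                    )
                    name = attrs.get("Target", attrs.get("Name", fields[2]))
                if start >= end:
                    raise AnnotationError(
                        f"{path}:{lineno}: start >= end ({start} >= {end})"
                    )
                family, klass, sub = parse_classification(name)
                ann = TEAnnotation(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    family_name=family,
                    te_class=klass,
                    te_subfamily=sub,
                    score=score,
                )
                if "kimura_div" in attrs:
                    ann.divergence = float(attrs["kimura_div"])
                if "age_my" in attrs:
                    ann.age_my = float(attrs["age_my"])
            except AnnotationError:
                raise
            except (IndexError, ValueError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            out.append(ann)
    return out


def write_te_annotations(
    annots: Iterable[TEAnnotation], path: str | Path, dialect: str = "bed"
) -> None:
    """Write annotations as BED6 or GFF3 (tab-separated, newline-terminated)."""
    if dialect not in ("bed", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
        for a in annots:
            score = f"{a.score:g}"
            if dialect == "bed":
                fh.write(
                    f"{a.chrom}\t{a.start}\t{a.end}\t{a.full_name}\t{score}\t{a.strand}\n"
                )
            else:
                attrs = [f"Target={a.full_name}"]
                if a.divergence is not None:
                    attrs.append(f"kimura_div={a.divergence:.6f}")
                if a.age_my is not None:
                    attrs.append(f"age_my={a.age_my:.4f}")
                fh.write(
                    f"{a.chrom}\trepeat\tdispersed_repeat\t{a.start + 1}\t{a.end}\t"
                    f"{score}\t{a.strand}\t.\t{';'.join(attrs)}\n"
                )


def read_consensus_library(path: str | Path) -> ConsensusLibrary:
    lib = ConsensusLibrary()
    for rec in SeqIO.parse(str(path), "fasta"):
        lib.add(rec.id, str(rec.seq))
    return lib


def write_consensus_library(lib: ConsensusLibrary, path: str | Path) -> None:
    records = []
    for family, seq in lib.entries.items():
        klass, sub = lib.te_class[family], lib.te_subfamily[family]
        name = f"{family}#{klass}" + (f"/{sub}" if sub else "")
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene + exon features, linked by Parent/ID)."""
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, ftype, start, end, strand = f[0], f[2], int(f[3]) - 1, int(f[4]), f[6]
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            if ftype == "gene":
                gid = attrs.get("ID", f"gene{len(genes)}")
                labels = [t for t in attrs.get("gene_set", "").split(",") if t]
                genes[gid] = GeneModel(gid, chrom, start, end, strand, [], labels)
            elif ftype == "exon":
                exons.setdefault(attrs.get("Parent", ""), []).append((start, end))
    out = []
    for gid, g in genes.items():
        out.append(replace(g, exons=sorted(exons.get(gid, []))))
    return out


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.gene_set_labels:
                attrs += f";gene_set={','.join(g.gene_set_labels)}"
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )


def read_gene_set(path: str | Path) -> list[str]:
    """Read a one-ID-per-line gene-set list (e.g. immune genes)."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# annotation post-processing filters


def filter_annotations(
    annots: list[TEAnnotation],
    min_length_bp: int = 100,
    min_score: float = 400.0,
) -> list[TEAnnotation]:
    """Drop short and low-scoring annotations.

    Records strictly shorter than ``min_length_bp`` (default 100 bp) or with
    score below ``min_score`` (default 400, the conservative mask-score
    cutoff) are removed; order is preserved.
    """
    if min_length_bp < 0 or min_score < 0:
        raise ValueError("thresholds must be non-negative")
    return [a for a in annots if a.length >= min_length_bp and a.score >= min_score]


def resolve_overlaps(annots: list[TEAnnotation]) -> list[TEAnnotation]:
    """Keep only the longest member of each maximal overlapping cluster.

    Clusters are transitive-overlap groups per chromosome (containment counts
    as overlap). Ties on length keep the record with the smaller start, so the
    result is deterministic and independent of input order. Input order of the
    retained records is preserved.
    """
    by_chrom: dict[str, list[tuple[int, TEAnnotation]]] = {}
    for idx, a in enumerate(annots):
        by_chrom.setdefault(a.chrom, []).append((idx, a))
    keep_idx: set[int] = set()
    for recs in by_chrom.values():
        recs.sort(key=lambda t: (t[1].start, t[1].end))
        cluster: list[tuple[int, TEAnnotation]] = []
        cluster_end = -1
        for idx, a in recs:
            if cluster and a.start >= cluster_end:
                keep_idx.add(_longest(cluster))
                cluster = []
                cluster_end = -1
            cluster.append((idx, a))
            cluster_end = max(cluster_end, a.end)
        if cluster:
            keep_idx.add(_longest(cluster))
    return [a for i, a in enumerate(annots) if i in keep_idx]


def _longest(cluster: list[tuple[int, TEAnnotation]]) -> int:
    best_idx, best = cluster[0]
    for idx, a in cluster[1:]:
        if a.length > best.length or (a.length == best.length and a.start < best.start):
            best_idx, best = idx, a
    return best_idx


def clean_annotations(
    annots: list[TEAnnotation],
    min_length_bp: int = 100,
    min_score: float = 400.0,
) -> list[TEAnnotation]:
    """Apply the standard post-processing: score/length filter, then overlap
    resolution. Filtering runs first so removed records cannot influence
    cluster membership."""
    return resolve_overlaps(filter_annotations(annots, min_length_bp, min_score))
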