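"""Intact (transposition-competent) LINE and PLE identification.

An intact LINE must be longer than 2700 bp and carry an ORF of more than
600 aa with start and stop codons and a reverse-transcriptase (RT) domain;
an intact PLE must be longer than 2400 bp (full-length PLEs are ~2500 bp)
and carry an ORF of more than 200 aa with both RT and GIY-YIG endonuclease
domains. Domain evidence is consumed as RPS-BLAST-style 12-column tabular
hits, so a live conserved-domain search is never required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

DOMAIN_VOCAB = ("RT", "GIY-YIG", "EN")
DEFAULT_DOMAIN_EVALUE = 0.01

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfRecord:
    """One open reading frame on a TE element (six-frame scan)."""

    element_id: str
    frame: int  # +1..+3, -1..-3
    aa_length: int
    has_start: bool
    has_stop: bool
    nt_start: int  # 0-based on the forward strand of the element
    nt_end: int
    protein: str = ""


@dataclass(frozen=True)
class DomainHit:
    orf_id: str
    domain: str  # RT | GIY-YIG | EN
    evalue: float
    start: int = 0
    end: int = 0


@dataclass(frozen=True)
class IntactnessRule:
    line_min_element_bp: int = 2700
    line_min_orf_aa: int = 600
    ple_min_element_bp: int = 2400
    ple_min_orf_aa: int = 200
    domain_evalue: float = DEFAULT_DOMAIN_EVALUE


@dataclass
class IntactCall:
    element_id: str
    decision: str  # intact_LINE | intact_PLE | not_intact
    reasons: list[str] = field(default_factory=list)


def find_orfs(
    sequence: str,
    min_aa: int = 1,
    require_start: bool = True,
    element_id: str = "element",
) -> list[OrfRecord]:
    """Six-frame ORF scan.

    With ``require_start`` an ORF runs from an ATG to the next in-frame stop
    (stop excluded from the aa length); otherwise from the frame start.
    ORFs shorter than ``min_aa`` are dropped. ORFs without a downstream stop
    run to the end of the frame with ``has_stop=False``.
    """
    seq = sequence.upper()
    n = len(seq)
    out: list[OrfRecord] = []
    for strand, s in ((1, seq), (-1, str(Seq(seq).reverse_complement()))):
        for off in range(3):
            codons = [s[i : i + 3] for i in range(off, len(s) - 2, 3)]
            i = 0
            while i < len(codons):
                if require_start:
                    while i < len(codons) and codons[i] != "ATG":
                        i += 1
                    if i >= len(codons):
                        break
                start_i = i
                while i < len(codons) and codons[i] not in _STOPS:
                    i += 1
                has_stop = i < len(codons)
                aa_len = i - start_i
                if aa_len >= min_aa:
                    nt_s = off + 3 * start_i
                    nt_e = off + 3 * (i + (1 if has_stop else 0))
                    if strand == -1:
                        nt_s, nt_e = n - nt_e, n - nt_s
                    protein = str(Seq("".join(codons[start_i:i])).translate())
                    out.append(
                        OrfRecord(
                            element_id=element_id,
                            frame=strand * (off + 1),
                            aa_length=aa_len,
                            has_start=codons[start_i] == "ATG",
                            has_stop=has_stop,
                            nt_start=nt_s,
                            nt_end=nt_e,
                            protein=protein,
                        )
                    )
                i += 1
    return out


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read domain hits from 12-column tabular output (query = ORF id,
    subject = domain name; e-value in column 11)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                DomainHit(
                    orf_id=f[0],
                    domain=_canonical_domain(f[1]),
                    evalue=float(f[10]),
                    start=int(f[6]) - 1,
                    end=int(f[7]),
                )
            )
    return out


def _canonical_domain(name: str) -> str:
    low = name.lower()
    if "giy" in low:
        return "GIY-YIG"
    if "rt" in low or "reverse" in low:
        return "RT"
    if low.startswith("en") or "endonuclease" in low:
        return "EN"
    return name


def _orf_id(element_id: str, k: int) -> str:
    return f"{element_id}.orf{k}"


def classify_intact(
    element_id: str,
    te_class: str,
    element_bp: int,
    orfs: list[OrfRecord],
    domain_hits: list[DomainHit],
    rule: IntactnessRule = IntactnessRule(),
) -> IntactCall:
    """Apply the intactness rules to one LINE or PLE element.

    Domain hits are matched to ORFs by orf_id (``<element_id>.orf<k>`` with
    k the index of the ORF in ``orfs``); only hits with e-value at or below
    the rule's gate count. The domain must fall within a qualifying ORF.
    """
    if te_class not in ("LINE", "PLE"):
        raise ValueError("intactness rules apply to LINE and PLE only")
    reasons: list[str] = []
    if te_class == "LINE":
        min_bp, min_aa = rule.line_min_element_bp, rule.line_min_orf_aa
    else:
        min_bp, min_aa = rule.ple_min_element_bp, rule.ple_min_orf_aa
    if element_bp <= min_bp:
        reasons.append(f"below {min_bp} bp extraction gate")
    domains_by_orf: dict[str, set[str]] = {}
    for h in domain_hits:
        if h.evalue <= rule.domain_evalue:
            domains_by_orf.setdefault(h.orf_id, set()).add(h.domain)
    qualifying = False
    for k, orf in enumerate(orfs):
        if orf.aa_length <= min_aa:
            continue
        doms = domains_by_orf.get(_orf_id(element_id, k), set())
        if te_class == "LINE":
            if orf.has_start and orf.has_stop and "RT" in doms:
                qualifying = True
                break
        else:
            if {"RT", "GIY-YIG"} <= doms:
                qualifying = True
                break
    if not qualifying:
        if te_class == "LINE":
            reasons.append(
                f"no ORF > {min_aa} aa with start codon, stop codon and RT domain"
            )
        else:
            reasons.append(f"no ORF > {min_aa} aa with RT and GIY-YIG domains")
    if reasons:
        return IntactCall(element_id, "not_intact", reasons)
    return IntactCall(element_id, f"intact_{te_class}", [])
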