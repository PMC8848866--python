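import numpy as np
import pytest
from Bio.Seq import Seq

from telandscape.intact import (
    DomainHit,
    IntactnessRule,
    classify_intact,
    find_orfs,
)

STOPS = {"TAA", "TAG", "TGA"}


def coding_sequence(n_codons, rng, with_start=True, with_stop=True):
    """Random ORF of n_codons sense codons (start included in the count)."""
    codons = []
    if with_start:
        codons.append("ATG")
    while len(codons) < n_codons:
        c = "".join(rng.choice(list("ACGT"), 3))
        if c not in STOPS and c != "ATG":
            codons.append(c)
    if with_stop:
        codons.append("TAA")
    return "".join(codons)


class TestFindOrfs:
    def test_constructed_orf_found(self, rng):
        seq = "CCC" + coding_sequence(650, rng) + "CCCCC"
        orfs = find_orfs(seq, min_aa=600)
        plus = [o for o in orfs if o.frame > 0]
        assert len(plus) == 1
        o = plus[0]
        assert o.aa_length == 650 and o.has_start and o.has_stop
        assert o.nt_start == 3 and o.nt_end == 3 + 651 * 3
        assert o.protein.startswith("M") and "*" not in o.protein

    def test_all_stops_empty(self):
        assert find_orfs("TAATAATAGTGA", min_aa=1) == []

    def test_strand_symmetry(self, rng):
        seq = "AAGG" + coding_sequence(100, rng) + "CCTT"
        rc = str(Seq(seq).reverse_complement())
        fwd = [o for o in find_orfs(seq, min_aa=100) if o.frame > 0]
        rev = [o for o in find_orfs(rc, min_aa=100) if o.frame < 0]
        assert len(fwd) == len(rev) == 1
        assert fwd[0].aa_length == rev[0].aa_length
        assert rev[0].protein == fwd[0].protein
        # coordinates mirror on the forward strand of the element
        assert rev[0].nt_start == len(seq) - fwd[0].nt_end

    def test_agrees_with_codon_walk_oracle(self, rng):
        # brute-force oracle: walk every frame on both strands
        for _ in range(200):
            n = int(rng.integers(30, 150))
            seq = "".join(rng.choice(list("ACGT"), n))
            got = {
                (o.frame, o.aa_length, o.has_start, o.has_stop)
                for o in find_orfs(seq, min_aa=2, require_start=True)
            }
            expected = set()
            for strand, s in ((1, seq), (-1, str(Seq(seq).reverse_complement()))):
                for off in range(3):
                    codons = [s[i : i + 3] for i in range(off, len(s) - 2, 3)]
                    i = 0
                    while i < len(codons):
                        if codons[i] == "ATG":
                            j = i
                            while j < len(codons) and codons[j] not in STOPS:
                                j += 1
                            aa = j - i
                            if aa >= 2:
                                expected.add((strand * (off + 1), aa, True, j < len(codons)))
                            i = j + 1
                        else:
                            i += 1
            assert got == expected


class TestClassifyIntact:
    def line_orf(self, rng, aa=650):
        seq = coding_sequence(aa, rng)
        return find_orfs(seq, min_aa=aa - 1)[0]

    def test_intact_line(self, rng):
        orfs = [self.line_orf(rng)]
        hits = [DomainHit("el.orf0", "RT", 1e-30)]
        call = classify_intact("el", "LINE", 3_000, orfs, hits)
        assert call.decision == "intact_LINE" and call.reasons == []

    def test_short_element_gated(self, rng):
        call = classify_intact("el", "LINE", 2_500, [self.line_orf(rng)],
                               [DomainHit("el.orf0", "RT", 1e-30)])
        assert call.decision == "not_intact"
        assert any("2700" in r for r in call.reasons)

    def test_boundary_length_excluded(self, rng):
        # "longer than 2700 bp": exactly 2700 fails the gate
        call = classify_intact("el", "LINE", 2_700, [self.line_orf(rng)],
                               [DomainHit("el.orf0", "RT", 1e-30)])
        assert call.decision == "not_intact"

    def test_ple_needs_both_domains(self, rng):
        orfs = find_orfs(coding_sequence(250, rng), min_aa=200)
        call = classify_intact("el", "PLE", 2_600, orfs,
                               [DomainHit("el.orf0", "RT", 1e-10)])
        assert call.decision == "not_intact"
        assert any("GIY-YIG" in r for r in call.reasons)
        call = classify_intact("el", "PLE", 2_600, orfs,
                               [DomainHit("el.orf0", "RT", 1e-10),
                                DomainHit("el.orf0", "GIY-YIG", 1e-5)])
        assert call.decision == "intact_PLE"

    def test_evalue_gate(self, rng):
        orfs = [self.line_orf(rng)]
        call = classify_intact("el", "LINE", 3_000, orfs,
                               [DomainHit("el.orf0", "RT", 0.5)])
        assert call.decision == "not_intact"

    def test_monotone_in_domain_hits(self, rng):
        orfs = [self.line_orf(rng)]
        base = [DomainHit("el.orf0", "RT", 1e-30)]
        extra = base + [DomainHit("el.orf0", "EN", 1e-10),
                        DomainHit("el.orf0", "GIY-YIG", 1e-4)]
        assert classify_intact("el", "LINE", 3_000, orfs, base).decision == "intact_LINE"
        assert classify_intact("el", "LINE", 3_000, orfs, extra).decision == "intact_LINE"

    def test_wrong_class_rejected(self):
        with pytest.raises(ValueError):
            classify_intact("el", "DNA", 3_000, [], [])

    def test_planted_precision_recall(self, rng):
        """Elements built with/without a qualifying ORF+domain pair are
        called perfectly."""
        tp = fp = fn = 0
        for i in range(20):
            intact = i % 2 == 0
            aa = 650 if intact else 400
            seq = coding_sequence(aa, rng)
            pad = "".join(rng.choice(list("ACGT"), max(0, 3000 - len(seq))))
            element = seq + pad
            orfs = find_orfs(element, min_aa=300)
            hits = (
                [DomainHit(f"el{i}.orf{k}", "RT", 1e-30) for k in range(len(orfs))]
                if intact
                else []
            )
            call = classify_intact(f"el{i}", "LINE", len(element), orfs, hits)
            if intact and call.decision == "intact_LINE":
                tp += 1
            elif intact:
                fn += 1
            elif call.decision == "intact_LINE":
                fp += 1
        assert tp == 10 and fp == 0 and fn == 0
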