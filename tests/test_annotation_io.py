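import pytest

from telandscape.annotation_io import (
    AnnotationError,
    TEAnnotation,
    filter_annotations,
    parse_classification,
    read_te_annotations,
    resolve_overlaps,
    write_te_annotations,
)


def make(chrom, start, end, score=500.0, name="tc1-1_dPle#DNA/TcMar-Tc1"):
    family, klass, sub = parse_classification(name)
    return TEAnnotation(chrom, start, end, "+", family, klass, sub, score)


@pytest.mark.parametrize(
    "name,family,klass,sub",
    [
        ("tc1-1_dPle#DNA/TcMar-Tc1", "tc1-1_dPle", "DNA", "TcMar-Tc1"),
        ("r2-hero_dPle#LINE/R2-Hero", "r2-hero_dPle", "LINE", "R2-Hero"),
        ("penelope-1_dPle#LINE/Penelope", "penelope-1_dPle", "PLE", "Penelope"),
        ("fam#RC/Helitron", "fam", "Rolling-circle", "Helitron"),
        ("fam#Unknown", "fam", "Unclassified", ""),
        ("no_suffix_at_all", "no_suffix_at_all", "Unclassified", ""),
        ("weird#ARTEFACT", "weird", "Other", ""),
    ],
)
def test_classification_parsing(name, family, klass, sub):
    assert parse_classification(name) == (family, klass, sub)


def test_bed_line_parses_to_annotation(tmp_path):
    p = tmp_path / "te.bed"
    p.write_text("chr1\t100\t600\ttc1-1_dPle#DNA/TcMar-Tc1\t412\t+\n")
    (ann,) = read_te_annotations(p, "bed")
    assert (ann.chrom, ann.start, ann.end) == ("chr1", 100, 600)
    assert ann.te_class == "DNA"
    assert ann.te_subfamily == "TcMar-Tc1"
    assert ann.score == 412
    assert ann.length == 500


def test_empty_file_gives_empty_list(tmp_path):
    p = tmp_path / "empty.bed"
    p.write_text("")
    assert read_te_annotations(p, "bed") == []


def test_malformed_coordinates_name_the_line(tmp_path):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t100\t600\tx\t1\t+\nchr1\t600\t600\tx\t1\t+\n")
    with pytest.raises(AnnotationError, match=":2"):
        read_te_annotations(p, "bed")


def test_unknown_dialect_is_usage_error(tmp_path):
    p = tmp_path / "x.bed"
    p.write_text("")
    with pytest.raises(ValueError, match="dialect"):
        read_te_annotations(p, "sam")


@pytest.mark.parametrize("dialect", ["bed", "gff3"])
def test_round_trip_is_lossless(tmp_path, dialect):
    annots = [
        make("chr1", 100, 600),
        make("chr1", 1000, 1400, name="r2-hero_dPle#LINE/R2-Hero", score=777),
        make("chr2", 5, 205, name="penelope-1_dPle#LINE/Penelope"),
        make("chr2", 300, 450, name="mystery"),
    ]
    p = tmp_path / f"rt.{dialect}"
    write_te_annotations(annots, p, dialect)
    back = read_te_annotations(p, dialect)
    for a, b in zip(annots, back):
        assert (a.chrom, a.start, a.end, a.strand) == (b.chrom, b.start, b.end, b.strand)
        assert (a.family_name, a.te_class, a.te_subfamily, a.score) == (
            b.family_name,
            b.te_class,
            b.te_subfamily,
            b.score,
        )


class TestFilter:
    def test_length_boundary(self):
        short = make("chr1", 0, 99)
        exact = make("chr1", 200, 300)
        out = filter_annotations([short, exact])
        assert out == [exact]

    def test_score_boundary(self):
        low = make("chr1", 0, 200, score=399)
        ok = make("chr1", 300, 500, score=400)
        assert filter_annotations([low, ok]) == [ok]

    def test_empty_input(self):
        assert filter_annotations([]) == []

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_annotations([], min_length_bp=-1)


class TestResolveOverlaps:
    def test_longest_of_pair_kept(self):
        a = make("chr1", 0, 500)
        b = make("chr1", 400, 700)
        assert resolve_overlaps([a, b]) == [a]

    def test_non_overlapping_kept(self):
        a = make("chr1", 0, 500)
        b = make("chr1", 500, 700)  # touching, half-open: no overlap
        assert resolve_overlaps([a, b]) == [a, b]

    def test_transitive_cluster_keeps_single_longest(self):
        a = make("chr1", 0, 1000)
        b = make("chr1", 900, 1200)
        c = make("chr1", 1150, 1400)
        assert resolve_overlaps([a, b, c]) == [a]

    def test_tie_keeps_smaller_start(self):
        a = make("chr1", 100, 400)
        b = make("chr1", 300, 600)
        assert resolve_overlaps([a, b]) == [a]
        assert resolve_overlaps([b, a]) == [a]

    def test_containment_counts_as_overlap(self):
        outer = make("chr1", 0, 1000)
        inner = make("chr1", 200, 400)
        assert resolve_overlaps([inner, outer]) == [outer]

    def test_output_never_overlaps(self, rng):
        annots = []
        for _ in range(300):
            s = int(rng.integers(0, 50_000))
            annots.append(make("chr1", s, s + int(rng.integers(100, 2000))))
        out = sorted(resolve_overlaps(annots), key=lambda a: a.start)
        for x, y in zip(out, out[1:]):
            assert x.end <= y.start

    def test_brute_force_cluster_oracle(self, rng):
        # independent oracle: explicit transitive closure on a small set
        annots = []
        for _ in range(40):
            s = int(rng.integers(0, 3000))
            annots.append(make("chr1", s, s + int(rng.integers(50, 800)), score=1))
        n = len(annots)
        adj = [[i] for i in range(n)]
        for i in range(n):
            for j in range(n):
                if i != j and annots[i].start < annots[j].end and annots[j].start < annots[i].end:
                    adj[i].append(j)
        # union-find closure
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in adj[i]:
                parent[find(i)] = find(j)
        clusters = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(i)
        expected = set()
        for members in clusters.values():
            best = max(
                members, key=lambda i: (annots[i].length, -annots[i].start)
            )
            expected.add(best)
        got = resolve_overlaps(annots)
        assert {id(a) for a in got} == {id(annots[i]) for i in expected}
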