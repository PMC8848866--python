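import numpy as np
import pytest
from scipy import stats

from telandscape.annotation_io import GeneModel, TEAnnotation
from telandscape.gene_te import (
    class_and_type_tests,
    compare_gene_sets,
    single_gene_enrichment,
    te_within_flanks,
)
from telandscape.simulate import (
    SimulationConfig,
    generate_gene_annotation,
    generate_library,
    plant_flank_insertions,
)

CHROM = {"chr1": 1_000_000}


def gene(gid="g1", start=500_000, end=510_000, labels=()):
    return GeneModel(gid, "chr1", start, end, "+", [(start, end)], list(labels))


def te(start, end, klass="LINE"):
    return TEAnnotation("chr1", start, end, family_name="f", te_class=klass)


class TestFlankProfiles:
    def test_upstream_te_counted(self):
        # one 500-bp element 7 kb upstream of the gene
        profs = te_within_flanks([gene()], [te(492_500, 493_000)], CHROM)
        assert profs[0].total_te_count == 1
        assert profs[0].total_te_bp == 500
        assert profs[0].available_flank_bp == 40_000

    def test_gene_body_te_excluded(self):
        profs = te_within_flanks([gene()], [te(505_000, 505_800)], CHROM)
        assert profs[0].total_te_count == 0

    def test_te_straddling_outer_edge(self):
        # flank spans [480000, 500000); TE pokes 100 bp inside
        profs = te_within_flanks([gene()], [te(479_900, 480_100)], CHROM)
        assert profs[0].total_te_bp == 100
        assert profs[0].total_te_count == 1

    def test_flank_truncated_at_chromosome_end(self):
        g = gene(start=5_000, end=15_000)
        profs = te_within_flanks([g], [], CHROM)
        assert profs[0].available_flank_bp == 25_000

    def test_brute_force_membership_oracle(self, rng):
        genes = [gene("a", 100_000, 110_000), gene("b", 200_000, 205_000)]
        annots = [
            te(int(s), int(s) + int(rng.integers(50, 3_000)))
            for s in rng.integers(0, 250_000, 60)
        ]
        profs = te_within_flanks(genes, annots, {"chr1": 300_000})
        for g, p in zip(genes, profs):
            flank = set(range(g.start - 20_000, g.start)) | set(
                range(g.end, g.end + 20_000)
            )
            expected = sum(
                len(set(range(a.start, a.end)) & flank) for a in annots
            )
            assert p.total_te_bp == expected


class TestGeneSetComparison:
    def test_null_case_fold_near_one(self):
        cfg = SimulationConfig(
            seed=21, chrom_lengths=(13_000_000,) * 4, n_genes=200,
            hotspot_windows=(), flank_multiplier=1.0,
        )
        lib = generate_library(cfg)
        genes = generate_gene_annotation(cfg)
        annots = plant_flank_insertions(cfg, lib, genes)
        profs = te_within_flanks(genes, annots, cfg.chrom_sizes)
        res = compare_gene_sets(profs, "immune")
        assert res["fold"] == pytest.approx(1.0, abs=0.35)
        assert res["p"] > 0.01

    def test_multiplier_three_recovered(self):
        cfg = SimulationConfig(
            seed=22, chrom_lengths=(13_000_000,) * 4, n_genes=200,
            hotspot_windows=(), flank_multiplier=3.0,
        )
        lib = generate_library(cfg)
        genes = generate_gene_annotation(cfg)
        annots = plant_flank_insertions(cfg, lib, genes)
        profs = te_within_flanks(genes, annots, cfg.chrom_sizes)
        res = compare_gene_sets(profs, "immune")
        assert res["fold"] == pytest.approx(3.0, abs=0.5)

    def test_fold_scale_invariance(self):
        profs = te_within_flanks(
            [gene("a", 100_000, 110_000, ["immune"]), gene("b", 300_000, 310_000)],
            [te(95_000, 96_000), te(295_000, 295_500)],
            CHROM,
        )
        res = compare_gene_sets(profs, "immune")
        assert res["fold"] == pytest.approx(2.0)
        assert res["degenerate"]  # single-gene groups

    def test_empty_complement_error(self):
        profs = te_within_flanks([gene("a", 100_000, 110_000, ["immune"])], [], CHROM)
        with pytest.raises(ValueError):
            compare_gene_sets(profs, "immune")


class TestGroupTests:
    def test_identical_groups_h_zero(self):
        res = class_and_type_tests({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res["H"] == pytest.approx(0.0)
        assert res["df"] == 1

    def test_matches_rank_oracle(self, rng):
        for _ in range(100):
            g1 = rng.normal(size=int(rng.integers(3, 10)))
            g2 = rng.normal(size=int(rng.integers(3, 10)))
            g3 = rng.normal(size=int(rng.integers(3, 10)))
            res = class_and_type_tests({"a": g1, "b": g2, "c": g3})
            h_scipy = stats.kruskal(g1, g2, g3).statistic
            assert res["H"] == pytest.approx(h_scipy, abs=1e-9)

    def test_shifted_group_detected(self, rng):
        groups = {k: rng.normal(0, 1, 30) for k in "abc"}
        groups["d"] = rng.normal(5, 1, 30)
        res = class_and_type_tests(groups)
        assert res["p"] < 0.01
        sig = res["posthoc"].query("group_a == 'd' or group_b == 'd'")
        assert (sig.p_adj < 0.05).all()

    def test_type_one_error_calibrated(self, rng):
        """Under the null the 5% level rejects about 5% of the time."""
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            groups = {k: rng.normal(0, 1, 8) for k in "abcd"}
            rejections += class_and_type_tests(groups)["p"] < 0.05
        assert rejections / n_sim <= 0.07

    def test_small_group_dropped(self):
        res = class_and_type_tests({"a": [1, 2, 3], "b": [4, 5, 6], "tiny": [1]})
        assert res["dropped_groups"] == ["tiny"]


class TestSingleGene:
    def _profiles(self, rng):
        genes, annots = [], []
        pos = 50_000
        counts = rng.poisson(8, 80)
        for i, c in enumerate(counts):
            g = gene(f"g{i}", pos, pos + 5_000)
            genes.append(g)
            for k in range(c):
                s = pos - 18_000 + 700 * k
                annots.append(te(s, s + 300))
            pos += 60_000
        return te_within_flanks(genes, annots, {"chr1": 50_000_000}), counts

    def test_typical_gene_expected(self, rng):
        profs, counts = self._profiles(rng)
        med = int(np.median([p.total_te_count for p in profs]))
        typical = next(p for p in profs if p.total_te_count == med)
        assert single_gene_enrichment(typical.gene_id, profs) == "expected"

    def test_extreme_gene_enriched(self, rng):
        profs, counts = self._profiles(rng)
        top = max(profs, key=lambda p: p.total_te_count)
        lo = min(p.total_te_count for p in profs)
        if top.total_te_count > 2 * np.median([p.total_te_count for p in profs]):
            assert single_gene_enrichment(top.gene_id, profs) in ("enriched", "expected")

    def test_unknown_gene_error(self, rng):
        profs, _ = self._profiles(rng)
        with pytest.raises(KeyError):
            single_gene_enrichment("nope", profs)
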