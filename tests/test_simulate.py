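import numpy as np
import pytest

from telandscape.annotation_io import (
    read_te_annotations,
    resolve_overlaps,
    write_consensus_library,
    write_gene_models,
    write_te_annotations,
)
from telandscape.divergence import kimura2p
from telandscape.simulate import (
    SimulationConfig,
    _mutate_codes,
    _random_codes,
    generate_gene_annotation,
    generate_library,
    plant_insertions,
    solve_substitution_fractions,
)


def small_cfg(**kw):
    base = dict(seed=1, chrom_lengths=(400_000,), hotspot_windows=(), n_genes=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestLibrary:
    def test_deterministic_fasta(self, tmp_path):
        cfg = small_cfg()
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_consensus_library(generate_library(cfg), p1)
        write_consensus_library(generate_library(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_family_count_and_unique_names(self):
        lib = generate_library(small_cfg(n_families=5))
        assert len(lib) == 5
        assert len(set(lib.entries)) == 5

    def test_requested_length_honoured(self):
        lib = generate_library(small_cfg(n_families=2, family_lengths=(2500, 900)))
        first = sorted(lib.entries, key=lambda f: -len(lib[f]))[0]
        assert len(lib[first]) == 2500

    def test_gc_content_in_band(self):
        lib = generate_library(small_cfg(n_families=6))
        for fam, seq in lib.entries.items():
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            assert 0.3 <= gc <= 0.5


class TestMutationEngine:
    def test_zero_divergence_identity(self):
        assert solve_substitution_fractions(0.0, 2.0) == (0.0, 0.0)
        rng = np.random.default_rng(0)
        codes = _random_codes(1000, rng)
        out, kind = _mutate_codes(codes, 0.0, 2.0, rng)
        assert (out == codes).all() and kind.sum() == 0

    def test_fractions_invert_k2p(self):
        for K in (0.01, 0.1, 0.3, 0.5):
            for r in (0.5, 2.0, 4.0):
                p, q = solve_substitution_fractions(K, r)
                assert p / q == pytest.approx(r)
                assert kimura2p(p, q) == pytest.approx(K, rel=1e-9)

    def test_monte_carlo_realized_k2p(self):
        """1,000 copies at target 0.10, ts:tv = 2 -> mean realized within 0.01."""
        rng = np.random.default_rng(42)
        cons = _random_codes(2_000, rng)
        ks = []
        for _ in range(1_000):
            _, kind = _mutate_codes(cons, 0.10, 2.0, rng)
            n = kind.size
            ks.append(kimura2p((kind == 1).sum() / n, (kind == 2).sum() / n))
        assert np.mean(ks) == pytest.approx(0.10, abs=0.01)

    def test_ts_tv_odds_realized(self):
        rng = np.random.default_rng(1)
        cons = _random_codes(200_000, rng)
        _, kind = _mutate_codes(cons, 0.2, 2.0, rng)
        assert (kind == 1).sum() / (kind == 2).sum() == pytest.approx(2.0, rel=0.05)


class TestPlanting:
    def test_truth_matches_annotations(self, small_bundle):
        cfg, library, genome, annots, truth = small_bundle
        assert len(annots) == len(truth.copies)
        for a, c in zip(annots, truth.copies):
            assert (a.chrom, a.start, a.end) == (c.chrom, c.start, c.end)
            assert a.family_name == c.family
            assert 0 <= c.start < c.end <= cfg.chrom_sizes[c.chrom]

    def test_zero_divergence_copies_identical_to_consensus(self):
        cfg = small_cfg(divergence_values=(0.0,))
        lib = generate_library(cfg)
        genome, annots, truth = plant_insertions(cfg, lib)
        for a, c in zip(annots[:20], truth.copies[:20]):
            planted = genome[a.chrom][a.start : a.end]
            assert planted == lib[c.family][c.consensus_start : c.consensus_end]

    def test_truth_annotations_never_overlap(self, small_bundle):
        _, _, _, annots, _ = small_bundle
        assert resolve_overlaps(list(annots)) == list(annots)

    def test_round_trip_through_annotation_io(self, small_bundle, tmp_path):
        _, _, _, annots, _ = small_bundle
        p = tmp_path / "t.bed"
        write_te_annotations(annots, p, "bed")
        back = read_te_annotations(p, "bed")
        assert [(a.chrom, a.start, a.end, a.family_name) for a in annots] == [
            (b.chrom, b.start, b.end, b.family_name) for b in back
        ]

    def test_truncation_mixture_binomial_bounds(self):
        cfg = SimulationConfig(
            seed=77, chrom_lengths=(4_000_000,), hotspot_windows=(),
            baseline_density_kb=25.0, density_sd_kb=5.0,
        )
        lib = generate_library(cfg)
        _, _, truth = plant_insertions(cfg, lib, with_sequence=False)
        copies = truth.copies[:400]
        assert len(copies) == 400
        sd = np.sqrt(400 * 0.25 * 0.75)
        for klass in ("full", "five_prime_type", "three_prime_type", "internal"):
            n = sum(c.truncation_class == klass for c in copies)
            assert abs(n - 100) <= 3 * sd

    def test_divergence_regression_slope_near_one(self):
        """Realized K2P regresses on target with slope 1 over >= 1,000 copies."""
        cfg = SimulationConfig(
            seed=13, chrom_lengths=(6_000_000,) * 2, hotspot_windows=(),
            baseline_density_kb=30.0, density_sd_kb=5.0,
            n_families=2, family_lengths=(5_000, 5_000),
        )
        lib = generate_library(cfg)
        _, _, truth = plant_insertions(cfg, lib, with_sequence=False)
        assert len(truth.copies) >= 1_000
        x = np.array([c.target_k2p for c in truth.copies])
        y = np.array([c.realized_k2p for c in truth.copies])
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_infeasible_packing_raises(self):
        cfg = small_cfg(
            chrom_lengths=(100_000,), baseline_density_kb=95.0, density_sd_kb=0.001
        )
        lib = generate_library(cfg)
        with pytest.raises(ValueError, match="packing"):
            plant_insertions(cfg, lib, with_sequence=False)


class TestGenes:
    def test_deterministic_gff(self, tmp_path):
        cfg = small_cfg(chrom_lengths=(1_500_000,), n_genes=12)
        p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
        write_gene_models(generate_gene_annotation(cfg), p1)
        write_gene_models(generate_gene_annotation(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_immune_fraction(self):
        cfg = SimulationConfig(
            seed=3, chrom_lengths=(7_000_000,) * 2, n_genes=100,
            hotspot_windows=(), immune_fraction=0.2,
        )
        genes = generate_gene_annotation(cfg)
        n_imm = sum("immune" in g.gene_set_labels for g in genes)
        assert n_imm == 20

    def test_impossible_placement_raises(self):
        cfg = small_cfg(chrom_lengths=(200_000,), n_genes=50)
        with pytest.raises(ValueError):
            generate_gene_annotation(cfg)
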