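"""End-to-end orchestration of the analysis stages over a synthetic bundle
or user-supplied inputs, with a manifest of every resolved parameter."""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .annotation_io import clean_annotations, write_te_annotations
from .compartments import build_compartments, te_compartment_overlap
from .deletions import classify_and_rate, species_specific_gaps
from .divergence import date_annotations, family_age_table, repeat_landscape
from .extremes import call_window_extremes, calls_to_bed
from .fragments import best_hit, classify_truncation, hits_to_table, turnover_summary
from .gene_te import compare_gene_sets, profiles_to_frame, te_within_flanks
from .simulate import SimulationConfig, generate_trio_blocks, plant_flank_insertions, simulate_genome
from .summaries import te_class_totals
from .windows import summarize_chromosomes, window_te_density, windows_to_bedgraph

ALL_STAGES = (
    "compartments",
    "windows",
    "extremes",
    "ages",
    "turnover",
    "intact",
    "deletions",
    "genesets",
)

_STAGE_DEPS = {"extremes": "windows"}


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run; defaults are the standard
    analysis values (100-kb windows, 20-kb flanks, 1/99% AUC quantiles,
    mu = 0.0116/site/My, 20-bp end tolerance, micro/mid deletion bounds at
    30 and 10,000 nt)."""

    seed: int = 0
    out_dir: str = "telandscape_run"
    window_bp: int = 100_000
    flank_width: int = 20_000
    lower_q: float = 0.01
    upper_q: float = 0.99
    poly_degree: int = 10
    n_bins: int = 100
    mu: float = 0.0116
    age_divisor: float = 1.0
    end_tolerance_bp: int = 20
    divergence_my: float = 8.3
    min_length_bp: int = 100
    min_score: float = 400.0
    #: simulation overrides (kept small so full runs stay quick)
    sim: dict = field(default_factory=lambda: {
        "chrom_lengths": (1_000_000,) * 4,
        "hotspot_windows": ((0, 3, 36.6), (2, 7, 36.6)),
        "n_genes": 60,
    })


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the requested stages on a freshly simulated bundle.

    Outputs land under ``config.out_dir`` with fixed names; a manifest
    records every resolved parameter, stage timing and output file, so
    identical config + seed gives identical outputs.
    """
    for st in stages:
        if st not in ALL_STAGES:
            raise ValueError(f"unknown stage {st!r}")
        dep = _STAGE_DEPS.get(st)
        if dep and dep not in stages:
            raise ValueError(f"stage {st!r} needs stage {dep!r} in the same run")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
    }

    sim_cfg = SimulationConfig(seed=config.seed, **config.sim)
    library, genome, annots, truth = simulate_genome(sim_cfg, with_sequence=True)
    annots = clean_annotations(annots, config.min_length_bp, config.min_score)
    chrom_sizes = sim_cfg.chrom_sizes
    genome_bp = sum(chrom_sizes.values())
    write_te_annotations(annots, out / "te_annotations.bed", "bed")
    totals = te_class_totals(annots, genome_bp)
    totals.to_csv(out / "class_totals.tsv", sep="\t", index=False)
    manifest["inputs"] = {
        "genome_bp": genome_bp,
        "n_annotations": len(annots),
        "n_families": len(library),
        "n_genes": len(truth.genes),
    }

    windows = None
    for stage in [s for s in ALL_STAGES if s in stages]:
        t0 = time.perf_counter()
        files: list[str] = []
        if stage == "compartments":
            cmap = build_compartments(truth.genes, chrom_sizes, config.flank_width)
            cmap.to_bed(out / "compartments.bed")
            te_compartment_overlap(annots, cmap).to_csv(
                out / "compartment_occupancy.tsv", sep="\t", index=False
            )
            files = ["compartments.bed", "compartment_occupancy.tsv"]
        elif stage == "windows":
            windows = window_te_density(annots, chrom_sizes, config.window_bp, truth.genes)
            windows_to_bedgraph(windows, out / "window_density.bedgraph")
            summ = summarize_chromosomes(windows)
            summ["per_chromosome"].to_csv(out / "chromosome_summary.tsv", sep="\t", index=False)
            (out / "window_stats.json").write_text(json.dumps({
                "mean_density_kb_per_100kb": summ["mean_density_kb_per_100kb"],
                "sd_density_kb_per_100kb": summ["sd_density_kb_per_100kb"],
            }, indent=1))
            files = ["window_density.bedgraph", "chromosome_summary.tsv", "window_stats.json"]
        elif stage == "extremes":
            calls = call_window_extremes(
                windows, config.lower_q, config.upper_q, config.poly_degree, config.n_bins
            )
            calls_to_bed(windows, calls, out / "extreme_windows.bed")
            (out / "extreme_thresholds.tsv").write_text(
                "cold_threshold\thot_threshold\tn_coldspots\tn_hotspots\n"
                f"{calls.cold_threshold:.4f}\t{calls.hot_threshold:.4f}\t"
                f"{calls.n_coldspots}\t{calls.n_hotspots}\n"
            )
            files = ["extreme_windows.bed", "extreme_thresholds.tsv"]
        elif stage == "ages":
            date_annotations(annots, genome, library, config.mu, config.age_divisor)
            write_te_annotations(annots, out / "te_annotations_dated.gff3", "gff3")
            family_age_table(annots).to_csv(out / "family_ages.tsv", sep="\t", index=False)
            repeat_landscape(annots, genome_bp).to_csv(
                out / "repeat_landscape.tsv", sep="\t", index=False
            )
            files = ["te_annotations_dated.gff3", "family_ages.tsv", "repeat_landscape.tsv"]
        elif stage == "turnover":
            hits, classes = [], []
            for i, a in enumerate(annots):
                if a.te_class not in ("LINE", "PLE"):
                    continue
                frag = genome[a.chrom][a.start : a.end]
                h = best_hit(frag, library, f"frag{i}")
                hits.append(h)
                classes.append(classify_truncation(h, config.end_tolerance_bp))
            hits_to_table(hits, classes, out / "fragment_classes.tsv")
            summary = turnover_summary(hits, classes)
            summary["per_group"].to_csv(out / "turnover_summary.tsv", sep="\t", index=False)
            (out / "turnover_stats.json").write_text(json.dumps({
                "percent_3prime_truncated": summary["percent_3prime_truncated"],
                "mean_fragment_length": summary["mean_fragment_length"],
                "n_fragments": summary["n_fragments"],
            }, indent=1))
            files = ["fragment_classes.tsv", "turnover_summary.tsv", "turnover_stats.json"]
        elif stage == "intact":
            from .intact import IntactnessRule, classify_intact, find_orfs

            rule = IntactnessRule()
            rows = ["element\tte_class\tlength_bp\tdecision\treasons"]
            for i, a in enumerate(annots):
                if a.te_class not in ("LINE", "PLE"):
                    continue
                seq = genome[a.chrom][a.start : a.end]
                min_aa = rule.line_min_orf_aa if a.te_class == "LINE" else rule.ple_min_orf_aa
                orfs = find_orfs(seq, min_aa + 1, True, f"el{i}")
                call = classify_intact(f"el{i}", a.te_class, a.length, orfs, [], rule)
                rows.append(
                    f"el{i}\t{a.te_class}\t{a.length}\t{call.decision}\t"
                    + ";".join(call.reasons)
                )
            (out / "intact_report.tsv").write_text("\n".join(rows) + "\n")
            files = ["intact_report.tsv"]
        elif stage == "deletions":
            blocks, _ = generate_trio_blocks(n_blocks=20, seed=config.seed)
            events = [e for b in blocks for e in species_specific_gaps(b)]
            rates = classify_and_rate(events, blocks, config.divergence_my)
            rates.to_frame().to_csv(out / "loss_rates.tsv", sep="\t", index=False)
            files = ["loss_rates.tsv"]
        elif stage == "genesets":
            import numpy as np

            flank_tes = plant_flank_insertions(
                sim_cfg, library, truth.genes, np.random.default_rng(config.seed + 3)
            )
            profiles = te_within_flanks(
                truth.genes, flank_tes, chrom_sizes, config.flank_width
            )
            profiles_to_frame(profiles).to_csv(out / "gene_flank_profiles.tsv", sep="\t", index=False)
            cmp_res = compare_gene_sets(profiles, "immune")
            (out / "gene_set_tests.json").write_text(json.dumps(cmp_res, indent=1))
            files = ["gene_flank_profiles.tsv", "gene_set_tests.json"]
        dt = time.perf_counter() - t0
        print(f"[telandscape] stage {stage}: {dt:.2f}s", file=sys.stderr)
        manifest["stages"][stage] = {"seconds": round(dt, 3), "outputs": files}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
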