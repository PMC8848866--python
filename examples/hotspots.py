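"""Windowed TE density and AUC-based hotspot/coldspot calling.

Chromosomes are split into 100-kb windows; a polynomial is fitted to the
density frequency distribution and windows beyond the 1%/99% cumulative-AUC
cutoffs are called coldspots/hotspots. The fold enrichment compares a
hotspot's density with the genome mean (an even spread of TEs).
"""

import warnings

from telandscape import call_window_extremes, fold_enrichment, window_te_density
from telandscape.simulate import SimulationConfig, generate_library, plant_insertions
from telandscape.windows import summarize_chromosomes

warnings.filterwarnings("ignore", message="polynomial fit")

cfg = SimulationConfig(seed=8)  # 10 x 25 Mb, 5 planted hotspot windows
library = generate_library(cfg)
_, annots, truth = plant_insertions(cfg, library, with_sequence=False)

windows = window_te_density(annots, cfg.chrom_sizes)
summary = summarize_chromosomes(windows)
calls = call_window_extremes(windows)

mean = summary["mean_density_kb_per_100kb"]
print(f"{len(windows)} windows, mean density {mean:.2f} kb/100 kb "
      f"(SD {summary['sd_density_kb_per_100kb']:.2f})")
print(f"thresholds: coldspot < {calls.cold_threshold:.2f}, "
      f"hotspot > {calls.hot_threshold:.2f} kb/100 kb")
print(f"called {calls.n_hotspots} hotspots and {calls.n_coldspots} coldspots")

hot = [w for w, lab in zip(windows, calls.labels) if lab == "hotspot"]
lowest = min(w.te_kb_per_100kb for w in hot)
print(f"lowest hotspot density {lowest:.2f} -> "
      f"{fold_enrichment(lowest, mean):.2f}x the even-spread expectation")
planted = {(cfg.chrom_name(ci), wi) for ci, wi, _ in cfg.hotspot_windows}
called = {(w.chrom, w.index) for w in hot}
print(f"planted hotspots recovered: {len(planted & called)}/{len(planted)}")
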