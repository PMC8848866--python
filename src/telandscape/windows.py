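"""Windowed TE/gene density and the association-test helpers.

Chromosomes are split into fixed, 0-anchored windows (default 100 kb); the
trailing short window is kept and its density is expressed per 100 kb using
its true width. A TE spanning a window boundary contributes bp to each
window it intersects, so window totals conserve annotated TE bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import TEAnnotation

DEFAULT_WINDOW = 100_000


@dataclass
class GenomeWindow:
    chrom: str
    index: int
    start: int
    end: int
    te_bp: int = 0
    gene_bp: int = 0

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def te_kb(self) -> float:
        return self.te_bp / 1000.0

    @property
    def te_kb_per_100kb(self) -> float:
        """Density normalised to the window's true width."""
        return self.te_bp / self.width * 100.0

    @property
    def gene_kb_per_100kb(self) -> float:
        return self.gene_bp / self.width * 100.0


def make_windows(
    chrom_sizes: dict[str, int],
    W: int = DEFAULT_WINDOW,
    min_chrom: int | None = None,
) -> list[GenomeWindow]:
    """Tile chromosomes with windows of width W (last window may be short).

    Sequences shorter than ``min_chrom`` (default W — sub-window scaffolds)
    are excluded, restricting per-chromosome analyses to chromosome-scale
    sequences.
    """
    if min_chrom is None:
        min_chrom = W
    out = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        if size < min_chrom:
            continue
        for i, s in enumerate(range(0, size, W)):
            out.append(GenomeWindow(chrom, i, s, min(s + W, size)))
    return out


def _accumulate(windows: list[GenomeWindow], intervals, attr: str, W: int) -> None:
    index = {}
    for w in windows:
        index.setdefault(w.chrom, {})[w.index] = w
    for chrom, start, end in intervals:
        if chrom not in index:
            continue
        for wi in range(start // W, (end - 1) // W + 1):
            w = index[chrom].get(wi)
            if w is None:
                continue
            bp = min(end, w.end) - max(start, w.start)
            if bp > 0:
                setattr(w, attr, getattr(w, attr) + bp)


def window_te_density(
    annots: list[TEAnnotation],
    chrom_sizes: dict[str, int],
    W: int = DEFAULT_WINDOW,
    genes=None,
) -> list[GenomeWindow]:
    """Per-window TE bp (and genic bp when gene models are given)."""
    windows = make_windows(chrom_sizes, W)
    _accumulate(windows, ((a.chrom, a.start, a.end) for a in annots), "te_bp", W)
    if genes is not None:
        _accumulate(windows, ((g.chrom, g.start, g.end) for g in genes), "gene_bp", W)
    return windows


def summarize_chromosomes(windows: list[GenomeWindow]) -> dict:
    """Per-chromosome TE totals plus the genome-wide mean and sample SD of
    window density (kb per 100 kb).

    A single window yields SD 0 with ``degenerate=True``.
    """
    if not windows:
        raise ValueError("no windows")
    dens = np.array([w.te_kb_per_100kb for w in windows])
    rows = []
    for chrom in sorted({w.chrom for w in windows}):
        ws = [w for w in windows if w.chrom == chrom]
        te_bp = sum(w.te_bp for w in ws)
        size = sum(w.width for w in ws)
        rows.append(
            {
                "chrom": chrom,
                "size_bp": size,
                "te_bp": te_bp,
                "n_windows": len(ws),
                "density_kb_per_100kb": te_bp / size * 100.0,
            }
        )
    degenerate = len(windows) < 2
    return {
        "per_chromosome": pd.DataFrame(rows),
        "mean_density_kb_per_100kb": float(dens.mean()),
        "sd_density_kb_per_100kb": 0.0 if degenerate else float(dens.std(ddof=1)),
        "degenerate": degenerate,
    }


def association_tests(x, y, kind: str):
    """Standard association tests used on window/gene summaries.

    kind: pearson | spearman (x, y numeric) or kruskal_wallis | welch_t
    (x numeric, y a grouping vector). Returns (statistic, df, p) where the
    statistic is r/rho for the correlations, H for Kruskal-Wallis (tie
    corrected, df = groups - 1) and t for Welch (Welch-Satterthwaite df).
    """
    x = np.asarray(x)
    if kind in ("pearson", "spearman"):
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("length mismatch")
        if len(x) < 3:
            raise ValueError("need >= 3 observations")
        if kind == "pearson":
            if np.std(x) == 0 or np.std(y) == 0:
                raise ValueError("zero variance: pearson undefined")
            r, p = stats.pearsonr(x.astype(float), y)
            return float(r), len(x) - 2, float(p)
        rho, p = stats.spearmanr(x.astype(float), y)
        return float(rho), len(x) - 2, float(p)
    if kind == "kruskal_wallis":
        groups = [np.asarray(x, dtype=float)[np.asarray(y) == g] for g in pd.unique(np.asarray(y))]
        if len(groups) < 2:
            raise ValueError("need >= 2 groups")
        h, p = stats.kruskal(*groups)
        return float(h), len(groups) - 1, float(p)
    if kind == "welch_t":
        labels = pd.unique(np.asarray(y))
        if len(labels) != 2:
            raise ValueError("welch_t needs exactly 2 groups")
        a = np.asarray(x, dtype=float)[np.asarray(y) == labels[0]]
        b = np.asarray(x, dtype=float)[np.asarray(y) == labels[1]]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        df = welch_satterthwaite_df(a, b)
        return float(t), float(df), float(p)
    raise ValueError(f"unknown test kind {kind!r}")


def welch_satterthwaite_df(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))


def windows_to_bedgraph(windows: list[GenomeWindow], path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.te_kb_per_100kb:.4f}\n")
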