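"""TE load around gene bodies and gene-set (immune) association tests.

Each gene gets a flank profile: TE bp and copy counts within ``w`` bp
(default 20 kb) either side of the gene body, gene body excluded, flanks
truncated at chromosome ends. Normalised coverage is TE bp over the flank
bp actually available, so genes near chromosome ends are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation_io import GeneModel, TEAnnotation
from .extremes import call_extremes, fit_density_curve
from .windows import welch_satterthwaite_df

DEFAULT_FLANK = 20_000


@dataclass
class GeneFlankProfile:
    gene_id: str
    gene_set_labels: list[str]
    available_flank_bp: int
    te_bp: dict[str, int] = field(default_factory=dict)  # per te_class
    te_count: dict[str, int] = field(default_factory=dict)

    @property
    def total_te_bp(self) -> int:
        return sum(self.te_bp.values())

    @property
    def total_te_count(self) -> int:
        return sum(self.te_count.values())

    @property
    def normalized_coverage(self) -> float:
        return self.total_te_bp / self.available_flank_bp


def te_within_flanks(
    genes: list[GeneModel],
    annots: list[TEAnnotation],
    chrom_sizes: dict[str, int],
    w: int = DEFAULT_FLANK,
    include_gene_body: bool = False,
) -> list[GeneFlankProfile]:
    """Per-gene TE bp and copy counts within the w-bp flanks.

    A TE partially overlapping a flank contributes only the overlapping bp
    and increments the copy count once per gene. ``include_gene_body``
    switches to a plain window search spanning the gene body as well.
    """
    by_chrom: dict[str, list[TEAnnotation]] = {}
    for a in annots:
        by_chrom.setdefault(a.chrom, []).append(a)
    for lst in by_chrom.values():
        lst.sort(key=lambda a: a.start)
    profiles = []
    for g in genes:
        size = chrom_sizes[g.chrom]
        regions = (
            [(max(0, g.start - w), min(size, g.end + w))]
            if include_gene_body
            else [
                r
                for r in ((max(0, g.start - w), g.start), (g.end, min(size, g.end + w)))
                if r[0] < r[1]
            ]
        )
        avail = sum(e - s for s, e in regions)
        prof = GeneFlankProfile(g.gene_id, list(g.gene_set_labels), avail)
        for a in by_chrom.get(g.chrom, []):
            bp = sum(
                max(0, min(a.end, e) - max(a.start, s)) for s, e in regions
            )
            if bp > 0:
                prof.te_bp[a.te_class] = prof.te_bp.get(a.te_class, 0) + bp
                prof.te_count[a.te_class] = prof.te_count.get(a.te_class, 0) + 1
        profiles.append(prof)
    return profiles


def compare_gene_sets(
    profiles: list[GeneFlankProfile],
    set_label: str = "immune",
    by_type: bool = False,
) -> dict:
    """Fold change of mean normalised flank coverage, set vs complement,
    with Welch's t-test.

    By default the observational unit is the gene; ``by_type`` averages
    within gene-set sub-labels first (group-level means, smaller n).
    """
    in_set = [p for p in profiles if set_label in p.gene_set_labels]
    out_set = [p for p in profiles if set_label not in p.gene_set_labels]
    if not in_set:
        raise ValueError(f"no genes labelled {set_label!r}")
    if not out_set:
        raise ValueError("complement gene set is empty")
    if by_type:
        a = _group_means(in_set, set_label)
        b = np.array([p.normalized_coverage for p in out_set])
    else:
        a = np.array([p.normalized_coverage for p in in_set])
        b = np.array([p.normalized_coverage for p in out_set])
    fold = float(a.mean() / b.mean()) if b.mean() > 0 else float("nan")
    degenerate = len(a) < 2 or len(b) < 2 or (a.var() == 0 and b.var() == 0)
    if degenerate:
        return {"fold": fold, "t": float("nan"), "df": float("nan"),
                "p": float("nan"), "degenerate": True, "unit": "type" if by_type else "gene"}
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "fold": fold,
        "t": float(t),
        "df": float(welch_satterthwaite_df(a, b)),
        "p": float(p),
        "degenerate": False,
        "unit": "type" if by_type else "gene",
    }


def _group_means(profiles: list[GeneFlankProfile], set_label: str) -> np.ndarray:
    groups: dict[str, list[float]] = {}
    for p in profiles:
        subs = [l for l in p.gene_set_labels if l != set_label] or [set_label]
        for s in subs:
            groups.setdefault(s, []).append(p.normalized_coverage)
    return np.array([float(np.mean(v)) for v in groups.values()])


def class_and_type_tests(
    values: dict[str, list[float]], min_group: int = 2
) -> dict:
    """Kruskal–Wallis across groups (TE classes or gene-set sub-labels) with
    pairwise rank-sum post-hoc contrasts, Benjamini–Hochberg adjusted.

    Groups with fewer than ``min_group`` observations are dropped with a
    warning entry in the result.
    """
    dropped = [g for g, v in values.items() if len(v) < min_group]
    kept = {g: np.asarray(v, dtype=float) for g, v in values.items() if len(v) >= min_group}
    if len(kept) < 2:
        raise ValueError("need >= 2 groups with enough observations")
    names = sorted(kept)
    h, p = stats.kruskal(*[kept[g] for g in names])
    pairs, raw_p = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            u, pu = stats.mannwhitneyu(kept[names[i]], kept[names[j]], alternative="two-sided")
            pairs.append((names[i], names[j]))
            raw_p.append(pu)
    adj = multipletests(raw_p, method="fdr_bh")[1] if raw_p else []
    posthoc = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "p_raw": raw_p,
            "p_adj": adj,
        }
    )
    return {
        "H": float(h),
        "df": len(names) - 1,
        "p": float(p),
        "posthoc": posthoc,
        "dropped_groups": dropped,
    }


def single_gene_enrichment(
    gene_id: str,
    profiles: list[GeneFlankProfile],
    lower_q: float = 0.025,
    upper_q: float = 0.975,
    degree: int = 10,
    n_bins: int = 100,
) -> str:
    """Label one gene depleted / expected / enriched by its flank TE copy
    number against AUC cutoffs over all genes' counts (central 95% by
    default). Comparisons are strict, so a count equal to a cutoff is
    "expected"."""
    counts = {p.gene_id: p.total_te_count for p in profiles}
    if gene_id not in counts:
        raise KeyError(f"unknown gene {gene_id!r}")
    calls = call_extremes(
        list(counts.values()), lower_q=lower_q, upper_q=upper_q,
        degree=degree, n_bins=n_bins,
    )
    label = calls.labels[list(counts).index(gene_id)]
    return {"coldspot": "depleted", "hotspot": "enriched"}.get(label, "expected")


def profiles_to_frame(profiles: list[GeneFlankProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "gene_id": p.gene_id,
                "gene_set": ",".join(p.gene_set_labels),
                "available_flank_bp": p.available_flank_bp,
                "te_bp": p.total_te_bp,
                "te_count": p.total_te_count,
                "normalized_coverage": p.normalized_coverage,
            }
        )
    return pd.DataFrame(rows)
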