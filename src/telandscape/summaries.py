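"""Repeat-content summary tables: per-class element counts, Mb and genome
percentages, plus comparisons between annotations."""

from __future__ import annotations

import pandas as pd

from .annotation_io import TE_CLASSES, TEAnnotation


def percent_of_genome(te_bp: float, genome_bp: float, decimals: int = 2) -> float:
    """Genome percentage occupied by te_bp, rounded to the reported precision."""
    if genome_bp <= 0:
        raise ValueError("genome size must be positive")
    return round(te_bp / genome_bp * 100.0, decimals)


def te_class_totals(annots: list[TEAnnotation], genome_bp: int) -> pd.DataFrame:
    """Per-class element counts, total length and percent of genome, with a
    total row (the standard repeat-content summary layout)."""
    rows = []
    total_n = total_bp = 0
    for klass in TE_CLASSES:
        sub = [a for a in annots if a.te_class == klass]
        bp = sum(a.length for a in sub)
        total_n += len(sub)
        total_bp += bp
        rows.append(
            {
                "te_class": klass,
                "n_elements": len(sub),
                "total_mb": bp / 1e6,
                "percent": percent_of_genome(bp, genome_bp),
            }
        )
    rows.append(
        {
            "te_class": "Total repeats",
            "n_elements": total_n,
            "total_mb": total_bp / 1e6,
            "percent": percent_of_genome(total_bp, genome_bp),
        }
    )
    return pd.DataFrame(rows)


def class_totals_from_mb(mb_by_class: dict[str, float], genome_mb: float) -> pd.DataFrame:
    """Class-total report from already-summed per-class Mb values (e.g. a
    published repeat-content table) and the assembly size in Mb."""
    rows = [
        {
            "te_class": klass,
            "total_mb": mb,
            "percent": percent_of_genome(mb, genome_mb),
        }
        for klass, mb in mb_by_class.items()
    ]
    return pd.DataFrame(rows)


def annotation_reduction(previous_percent: float, current_percent: float) -> float:
    """Percentage-point reduction of repeat content between two annotations
    of the same assembly."""
    return round(previous_percent - current_percent, 2)
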