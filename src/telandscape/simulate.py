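"""Synthetic genomes with planted TE copies, genes, hotspots and ortholog trios.

Every generator is deterministic under a fixed seed and returns full ground
truth, so each analysis stage can be tested for recovery without any
external data. The defaults encode the study conditions the analyses are
designed around: 2,500 100-kb windows whose baseline TE density is gamma
distributed with mean 6.1 and SD 4.1 kb/100 kb (a continuous, right-skewed
between-window profile) plus five planted hotspot windows at six times the
mean, well clear of the baseline tail; copy divergences
targeting requested Kimura 2-parameter values with transition:transversion
odds 2; a four-way truncation mixture (full / 5'-type / 3'-type / internal)
in equal parts; a neutral rate of 0.0116 substitutions/site/My; immune-gene
flanks carrying three times the baseline TE load; and ~10 kb ortholog
blocks bearing species-specific micro (< 30 nt) and mid-size deletions in
an equal nucleotide split.

The mutation engine draws substitutions only: planted copies are contiguous
consensus slices with point differences, so K2P dating and truncation
classes are exactly recoverable. Background sequence is i.i.d. uniform over
{A,C,G,T}. An indel-bearing copy mode exists but defaults off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .annotation_io import ConsensusLibrary, GeneModel, TEAnnotation
from .divergence import DEFAULT_NEUTRAL_RATE, kimura2p

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TRUNCATION_MIX_DEFAULT = {
    "full": 0.25,
    "five_prime_type": 0.25,
    "three_prime_type": 0.25,
    "internal": 0.25,
}

_FAMILY_CLASS_CYCLE = ("LINE", "PLE", "DNA", "SINE", "LTR", "Rolling-circle")
_CLASS_SUBFAMILY = {
    "LINE": "R2-Hero",
    "PLE": "Penelope",
    "DNA": "TcMar-Tc1",
    "SINE": "tRNA",
    "LTR": "Gypsy",
    "Rolling-circle": "Helitron",
}
_CLASS_LENGTH = {
    "LINE": 4500,
    "PLE": 2500,
    "DNA": 1300,
    "SINE": 300,
    "LTR": 6000,
    "Rolling-circle": 2000,
}


@dataclass
class SimulationConfig:
    """Knobs for the synthetic genome; defaults are the standard conditions."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (25_000_000,) * 10
    n_families: int = 6
    family_lengths: tuple[int, ...] | None = None  # default per-class lengths
    ts_tv_ratio: float = 2.0
    divergence_range: tuple[float, float] = (0.01, 0.40)  # per-copy target K2P
    divergence_values: tuple[float, ...] | None = None  # overrides the range
    truncation_mix: dict = field(default_factory=lambda: dict(TRUNCATION_MIX_DEFAULT))
    window_bp: int = 100_000
    baseline_density_kb: float = 6.1  # mean TE kb per 100 kb window
    density_sd_kb: float = 4.1  # between-window SD of the baseline density
    #: (chrom index, window index, target density kb/100 kb)
    hotspot_windows: tuple[tuple[int, int, float], ...] = (
        (0, 11, 36.6),
        (1, 48, 36.6),
        (2, 85, 36.6),
        (3, 122, 36.6),
        (4, 159, 36.6),
    )
    n_genes: int = 200
    gene_length: int = 8_000
    n_exons: int = 4
    exon_length: int = 600
    immune_fraction: float = 0.1
    flank_multiplier: float = 3.0
    flank_width: int = 20_000
    mu: float = DEFAULT_NEUTRAL_RATE
    indel_mode: bool = False
    indel_rate: float = 0.002  # per site, only when indel_mode is on

    def __post_init__(self) -> None:
        if abs(sum(self.truncation_mix.values()) - 1.0) > 1e-9:
            raise ValueError("truncation mixture must sum to 1")
        if self.ts_tv_ratio <= 0 or self.mu <= 0:
            raise ValueError("rates must be positive")

    def chrom_name(self, i: int) -> str:
        return f"chr{i + 1}"

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {self.chrom_name(i): n for i, n in enumerate(self.chrom_lengths)}


@dataclass
class PlantedCopy:
    family: str
    chrom: str
    start: int
    end: int
    target_k2p: float
    realized_k2p: float
    truncation_class: str
    consensus_start: int
    consensus_end: int

    @property
    def age_my(self) -> float:
        return self.realized_k2p / DEFAULT_NEUTRAL_RATE


@dataclass
class SyntheticTruth:
    """Ground truth for every planted feature of a synthetic genome."""

    copies: list[PlantedCopy] = field(default_factory=list)
    #: (chrom, window index) -> planted target density kb/100 kb
    window_density: dict = field(default_factory=dict)
    genes: list[GeneModel] = field(default_factory=list)
    #: (block_id, species, start_col, length)
    deletions: list[tuple[str, str, int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# mutation engine


def solve_substitution_fractions(K: float, ts_tv_ratio: float) -> tuple[float, float]:
    """Transition/transversion site fractions (p, q) whose K2P distance is K
    with p/q = ts_tv_ratio."""
    if K == 0:
        return 0.0, 0.0
    r = ts_tv_ratio
    q_hi = min(0.5, 1.0 / (2.0 * r + 1.0)) - 1e-9

    def f(q: float) -> float:
        return kimura2p(r * q, q) - K

    q = brentq(f, 1e-12, q_hi)
    return r * q, q


def _mutate_codes(
    codes: np.ndarray, K: float, ts_tv_ratio: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Apply point substitutions to a base-code array targeting K2P = K.

    Returns (mutated codes, per-site change type: 0 none, 1 transition,
    2 transversion).
    """
    p, q = solve_substitution_fractions(K, ts_tv_ratio)
    u = rng.random(codes.size)
    kind = np.zeros(codes.size, dtype=np.uint8)
    kind[u < p] = 1
    kind[(u >= p) & (u < p + q)] = 2
    out = codes.copy()
    ts = kind == 1
    out[ts] = (codes[ts] + 2) % 4  # A<->G, C<->T
    tv = kind == 2
    coin = rng.integers(0, 2, int(tv.sum()))
    out[tv] = (codes[tv] + np.where(coin == 0, 1, 3)) % 4
    return out, kind


def _realized_k2p(kind_slice: np.ndarray) -> float:
    n = kind_slice.size
    if n == 0:
        return 0.0
    P = float((kind_slice == 1).sum()) / n
    Q = float((kind_slice == 2).sum()) / n
    return kimura2p(P, Q)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _str_to_codes(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _random_codes(n: int, rng: np.random.Generator, gc: float | None = None) -> np.ndarray:
    if gc is None:
        return rng.integers(0, 4, n, dtype=np.uint8)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


# ---------------------------------------------------------------------------
# generators


def generate_library(config: SimulationConfig) -> ConsensusLibrary:
    """A consensus library of ``n_families`` with realistic per-class lengths
    and GC content near 0.4."""
    if config.n_families < 1:
        raise ValueError("need at least one family")
    rng = np.random.default_rng(config.seed)
    lib = ConsensusLibrary()
    for i in range(config.n_families):
        klass = _FAMILY_CLASS_CYCLE[i % len(_FAMILY_CLASS_CYCLE)]
        length = (
            config.family_lengths[i]
            if config.family_lengths is not None
            else _CLASS_LENGTH[klass]
        )
        name = f"{klass.lower()}-{i + 1}_sim#{_suffix(klass)}"
        lib.add(name, _codes_to_str(_random_codes(length, rng, gc=0.4)))
    return lib


def _suffix(klass: str) -> str:
    head = {"Rolling-circle": "RC", "PLE": "LINE"}.get(klass, klass)
    sub = _CLASS_SUBFAMILY[klass]
    return f"{head}/{sub}"


def _truncate(
    cons_len: int, klass: str, rng: np.random.Generator
) -> tuple[int, int]:
    """Consensus slice retained by a copy of the given truncation class.

    5'-type copies lose a uniform 10-70% suffix (they keep the 5' end);
    3'-type copies lose a prefix; internal copies lose both ends.
    """
    if klass == "full":
        return 0, cons_len
    if klass == "five_prime_type":
        lost = rng.uniform(0.10, 0.70)
        return 0, max(1, int(round(cons_len * (1 - lost))))
    if klass == "three_prime_type":
        lost = rng.uniform(0.10, 0.70)
        return min(cons_len - 1, int(round(cons_len * lost))), cons_len
    lost5 = rng.uniform(0.10, 0.35)
    lost3 = rng.uniform(0.10, 0.35)
    s = int(round(cons_len * lost5))
    e = int(round(cons_len * (1 - lost3)))
    return s, max(s + 1, e)


def plant_insertions(
    config: SimulationConfig,
    library: ConsensusLibrary,
    with_sequence: bool = True,
) -> tuple[dict[str, str], list[TEAnnotation], SyntheticTruth]:
    """Plant mutated, truncated TE copies window by window.

    Each 100-kb window receives copies until its planted TE bp reaches the
    window's target density (baseline, or the hotspot target for windows
    listed in ``hotspot_windows``). Copies never overlap. With
    ``with_sequence=False`` only annotations and truth are produced (the
    genome dict is empty), which keeps large window-statistics fixtures
    cheap.
    """
    rng = np.random.default_rng(config.seed + 1)
    families = sorted(library.entries)
    cons_codes = {f: _str_to_codes(library[f]) for f in families}
    mix_names = list(config.truncation_mix)
    mix_p = np.array([config.truncation_mix[k] for k in mix_names])
    hot = {
        (config.chrom_name(ci), wi): dens for ci, wi, dens in config.hotspot_windows
    }
    truth = SyntheticTruth()
    genome: dict[str, str] = {}
    annots: list[TEAnnotation] = []
    W = config.window_bp
    for ci, chrom_len in enumerate(config.chrom_lengths):
        chrom = config.chrom_name(ci)
        chrom_codes = _random_codes(chrom_len, rng) if with_sequence else None
        for wi, wstart in enumerate(range(0, chrom_len, W)):
            wend = min(wstart + W, chrom_len)
            width = wend - wstart
            target_dens = hot.get((chrom, wi))
            if target_dens is None:
                # gamma-distributed baseline: right-skewed, continuous tail,
                # moments matching the configured mean and SD
                shape = (config.baseline_density_kb / config.density_sd_kb) ** 2
                scale = config.density_sd_kb**2 / config.baseline_density_kb
                target_dens = float(rng.gamma(shape, scale))
            truth.window_density[(chrom, wi)] = target_dens
            target_bp = target_dens * 1000.0 * width / W
            copies = _draw_window_copies(
                target_bp, families, cons_codes, mix_names, mix_p, config, rng
            )
            total = sum(e - s for _, s, e, _ in copies)
            if total > 0.8 * width:
                raise ValueError(
                    f"infeasible packing in {chrom} window {wi}: "
                    f"{total} planted bp in {width} bp"
                )
            placements = _place(copies, width, rng)
            for (family, cs, ce, klass), pos in placements:
                start = wstart + pos
                end = start + (ce - cs)
                target_k = _draw_target_k(config, rng)
                mutated, kinds = _mutate_codes(
                    cons_codes[family], target_k, config.ts_tv_ratio, rng
                )
                copy_codes = mutated[cs:ce]
                realized = _realized_k2p(kinds[cs:ce])
                if with_sequence:
                    chrom_codes[start:end] = copy_codes
                annots.append(
                    TEAnnotation(
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand="+",
                        family_name=family,
                        te_class=library.te_class[family],
                        te_subfamily=library.te_subfamily[family],
                        score=1000.0,
                    )
                )
                truth.copies.append(
                    PlantedCopy(
                        family=family,
                        chrom=chrom,
                        start=start,
                        end=end,
                        target_k2p=target_k,
                        realized_k2p=realized,
                        truncation_class=klass,
                        consensus_start=cs,
                        consensus_end=ce,
                    )
                )
        if with_sequence:
            genome[chrom] = _codes_to_str(chrom_codes)
    return genome, annots, truth


def _draw_target_k(config: SimulationConfig, rng: np.random.Generator) -> float:
    if config.divergence_values is not None:
        return float(rng.choice(np.asarray(config.divergence_values)))
    lo, hi = config.divergence_range
    return float(rng.uniform(lo, hi))


def _draw_window_copies(target_bp, families, cons_codes, mix_names, mix_p, config, rng):
    """Pick (family, consensus slice, truncation class) tuples whose total
    length approaches target_bp."""
    copies = []
    total = 0
    # expected copy length ~ half a consensus; cap the loop defensively
    for _ in range(10_000):
        if total >= target_bp:
            break
        family = families[rng.integers(len(families))]
        klass = mix_names[int(rng.choice(len(mix_names), p=mix_p))]
        cs, ce = _truncate(len(cons_codes[family]), klass, rng)
        if total + (ce - cs) > 1.2 * target_bp and copies:
            break
        copies.append((family, cs, ce, klass))
        total += ce - cs
    return copies


def _place(copies, width, rng):
    """Non-overlapping placement of copies inside a window: the free space
    is split into n+1 gaps by a symmetric Dirichlet draw."""
    if not copies:
        return []
    lengths = [ce - cs for _, cs, ce, _ in copies]
    free = width - sum(lengths)
    if free < 0:
        raise ValueError("infeasible packing")
    gaps = rng.multinomial(free, np.full(len(copies) + 1, 1.0 / (len(copies) + 1)))
    placements = []
    pos = 0
    for copy, gap, length in zip(copies, gaps[:-1], lengths):
        pos += int(gap)
        placements.append((copy, pos))
        pos += length
    return placements


def generate_gene_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Evenly spaced, non-overlapping gene models with a configurable
    fraction tagged "immune" (plus an immune sub-type label)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    total = sum(config.chrom_lengths)
    spacing = total // max(1, config.n_genes)
    min_spacing = config.gene_length + 2 * config.flank_width + 1000
    if spacing < min_spacing:
        raise ValueError(
            f"cannot place {config.n_genes} genes of {config.gene_length} bp "
            f"with {config.flank_width} bp flanks without overlap"
        )
    n_immune = int(round(config.immune_fraction * config.n_genes))
    immune_ids = set(rng.choice(config.n_genes, size=n_immune, replace=False).tolist())
    immune_types = ("CLIP", "IMD", "IKK", "SOCS", "Tab2")
    genes = []
    gi = 0
    for ci, chrom_len in enumerate(config.chrom_lengths):
        chrom = config.chrom_name(ci)
        pos = config.flank_width + 500
        while gi < config.n_genes and pos + config.gene_length + config.flank_width < chrom_len:
            start = pos + int(rng.integers(0, 500))
            end = start + config.gene_length
            exons = _exon_layout(start, end, config.n_exons, config.exon_length)
            labels = []
            if gi in immune_ids:
                labels = ["immune", immune_types[gi % len(immune_types)]]
            genes.append(
                GeneModel(f"gene{gi:04d}", chrom, start, end, "+", exons, labels)
            )
            gi += 1
            pos = end + 2 * config.flank_width + 1000
        if gi >= config.n_genes:
            break
    if gi < config.n_genes:
        raise ValueError("chromosomes too short to place all genes")
    return genes


def _exon_layout(start: int, end: int, n_exons: int, exon_len: int) -> list:
    span = end - start
    if n_exons * exon_len >= span:
        return [(start, end)]
    intron = (span - n_exons * exon_len) // max(1, n_exons - 1) if n_exons > 1 else 0
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append((pos, pos + exon_len))
        pos += exon_len + intron
    # stretch the final exon to stay inside the span exactly
    s, _ = exons[-1]
    exons[-1] = (s, min(s + exon_len, end))
    return exons


def plant_flank_insertions(
    config: SimulationConfig,
    library: ConsensusLibrary,
    genes: list[GeneModel],
    rng: np.random.Generator | None = None,
) -> list[TEAnnotation]:
    """Plant TEs in gene flanks only: immune-gene flanks receive
    ``flank_multiplier`` times the baseline density, other flanks baseline.

    Copy counts per flank are Poisson, so measured immune/other fold ratios
    converge on the multiplier as gene count grows.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    sizes = config.chrom_sizes
    families = sorted(library.entries)
    annots = []
    dens_per_bp = config.baseline_density_kb * 1000.0 / config.window_bp
    for g in genes:
        mult = config.flank_multiplier if "immune" in g.gene_set_labels else 1.0
        for s, e in (
            (max(0, g.start - config.flank_width), g.start),
            (g.end, min(sizes[g.chrom], g.end + config.flank_width)),
        ):
            if e <= s:
                continue
            mean_len = 500
            n = rng.poisson(dens_per_bp * mult * (e - s) / mean_len)
            copies = []
            for _ in range(n):
                family = families[rng.integers(len(families))]
                cons_len = len(library[family])
                cs, ce = _truncate(cons_len, "internal", rng)
                length = min(ce - cs, mean_len)
                copies.append((family, cs, cs + length, "internal"))
            total = sum(ce - cs for _, cs, ce, _ in copies)
            if total >= (e - s):
                copies = copies[: max(1, len(copies) // 2)]
            for (family, cs, ce, klass), pos in _place(copies, e - s, rng):
                annots.append(
                    TEAnnotation(
                        chrom=g.chrom,
                        start=s + pos,
                        end=s + pos + (ce - cs),
                        strand="+",
                        family_name=family,
                        te_class=library.te_class[family],
                        te_subfamily=library.te_subfamily[family],
                        score=1000.0,
                    )
                )
    return annots


def generate_ortholog_trio(
    block_length: int = 10_000,
    del_nt_per_10kb: dict[str, float] | float = 176.5,
    micro_nt_fraction: float = 0.5,
    substitution_rate: float = 0.02,
    seed: int = 0,
    block_id: str = "block",
):
    """One aligned trio block (outgroup + ingroups A, B) with planted
    species-specific deletions.

    ``del_nt_per_10kb`` is the expected deleted-nucleotide load per species
    (a dict {"A": x, "B": y} or one number for both); ``micro_nt_fraction``
    splits that load between micro (< 30 nt) and mid-size events. Deletions
    appear as gap runs in exactly one ingroup row; the outgroup is gap-free.
    Returns (rows dict name->aligned string, truth event list
    [(block_id, species, start_col, length)]).
    """
    rng = np.random.default_rng(seed)
    if not isinstance(del_nt_per_10kb, dict):
        del_nt_per_10kb = {"A": del_nt_per_10kb, "B": del_nt_per_10kb}
    out_codes = _random_codes(block_length, rng)
    rows = {"outgroup": _codes_to_str(out_codes)}
    # carve disjoint alternating slots so planted runs are never shared
    slots = {"A": [], "B": []}
    slot_w = 400
    for i, s in enumerate(range(0, block_length - slot_w, slot_w)):
        slots["A" if i % 2 == 0 else "B"].append((s + 20, s + slot_w - 20))
    truth = []
    for sp in ("A", "B"):
        codes, _ = _mutate_codes(out_codes, substitution_rate, 2.0, rng)
        row = np.frombuffer(_codes_to_str(codes).encode(), dtype=np.uint8).copy()
        load = del_nt_per_10kb[sp] * block_length / 10_000.0
        events = _draw_deletions(load, micro_nt_fraction, rng)
        free_slots = list(slots[sp])
        rng.shuffle(free_slots)
        for length in events:
            slot = next(
                (t for t in free_slots if t[1] - t[0] >= length), None
            )
            if slot is None:
                continue
            free_slots.remove(slot)
            s0 = int(rng.integers(slot[0], slot[1] - length + 1))
            row[s0 : s0 + length] = ord("-")
            truth.append((block_id, sp, s0, int(length)))
        rows[sp] = row.tobytes().decode()
    return rows, truth


def _draw_deletions(load_nt: float, micro_frac: float, rng) -> list[int]:
    """Event lengths whose expected total is ``load_nt``, split micro/mid."""
    lengths = []
    micro_mean = 15.0  # uniform 1..29
    mid_mean = 165.0  # uniform 30..300
    for n_mean, lo, hi in (
        (load_nt * micro_frac / micro_mean, 1, 29),
        (load_nt * (1 - micro_frac) / mid_mean, 30, 300),
    ):
        for _ in range(rng.poisson(n_mean)):
            lengths.append(int(rng.integers(lo, hi + 1)))
    return lengths


def generate_trio_blocks(
    n_blocks: int = 100,
    block_length: int = 10_000,
    del_nt_per_10kb: dict[str, float] | float = 176.5,
    micro_nt_fraction: float = 0.5,
    seed: int = 0,
):
    """A set of trio blocks plus the combined truth list."""
    from .deletions import OrthologBlock

    blocks, truth = [], []
    for i in range(n_blocks):
        rows, t = generate_ortholog_trio(
            block_length=block_length,
            del_nt_per_10kb=del_nt_per_10kb,
            micro_nt_fraction=micro_nt_fraction,
            seed=seed * 1_000_003 + i,
            block_id=f"block{i:04d}",
        )
        blocks.append(
            OrthologBlock(f"block{i:04d}", rows["outgroup"], rows["A"], rows["B"])
        )
        truth.extend(t)
    return blocks, truth


def simulate_genome(config: SimulationConfig, with_sequence: bool = True):
    """Full synthetic bundle: library, genome, TE annotations, genes, truth."""
    library = generate_library(config)
    genome, annots, truth = plant_insertions(config, library, with_sequence)
    rng = np.random.default_rng(config.seed + 2)
    try:
        truth.genes = generate_gene_annotation(config, rng)
    except ValueError:
        truth.genes = []
    return library, genome, annots, truth
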