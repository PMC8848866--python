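# Methods

This note documents the models, conventions and design choices behind
`telandscape`, in the order the pipeline runs them.

## Coordinates and annotation filters

All in-memory intervals are 0-based half-open; GFF3 (1-based inclusive) is
converted at the I/O boundary only, so no stage ever mixes conventions.
TE classification strings follow the RepeatMasker convention
`family#Class/Subclass`; `LINE/Penelope` names are reported as the PLE
class, matching how repeat summaries separate Penelope-like elements from
other LINEs, and unparseable suffixes map to Unclassified.

Annotation cleaning applies a mask-score floor (default 400, a conservative
level that excludes poor matches unlikely to be real TE sequence) and a
length floor (default 100 bp, dropping fragments too short to identify
confidently). The length rule reads "strictly shorter than 100 bp is
removed": a 100-bp record is kept. Overlap resolution operates on maximal
transitive-overlap clusters per chromosome — containment counts as overlap —
and keeps exactly the longest member, breaking length ties toward the
smaller start so the result is order-independent. Filtering runs before
overlap resolution, so a record removed by the score/length gates can no
longer link two clusters together.

## Compartments

Each chromosome is tiled exactly by exon, intron, flank and intergenic
intervals. Introns are the gene span minus the exon union; flanks extend
20 kb either side of a gene body (the proximate-promoter scale, covering
promoter plus distal enhancers) truncated at chromosome ends. On conflict
the priority is exon > intron > flank > intergenic: a base inside one
gene's body and another gene's flank is genic, and overlapping flanks of
adjacent genes merge. This makes the partition well-defined; the sum of
label lengths equals the chromosome length by construction, which the
tests assert exactly. TE occupancy splits each copy's bp across every
compartment it intersects, so per-class bp is conserved.

## Windows and extremes

Windows are 0-anchored, 100 kb wide, with the trailing short window kept
and densities expressed per 100 kb of true window width; sequences shorter
than one window are excluded from per-chromosome summaries. The
hotspot/coldspot caller fits a least-squares polynomial (default degree 10,
100 histogram bins, both exposed) through the (bin midpoint, count) points
of the density frequency distribution, clamps negative fitted values to
zero, and accumulates the area under the clamped curve left to right on a
2,000-point grid. The cold threshold is the largest grid density whose
cumulative AUC stays at or below 1% of the total; the hot threshold
likewise at 99% (2.5%/97.5% for per-gene TE counts, the central 95%).
Label comparisons are strict, so boundary values are "normal". The fit is
to histogram bins rather than sorted raw values (recorded in the curve
object); the fit warns when absolute residuals exceed 10% of the count
mass, which is expected when the distribution carries an isolated extreme
bump. Fold enrichment is observed density over the genome-mean window
density, reported to two decimals.

## K2P dating

Copies are compared with their family consensus over gap-free columns
(columns with `-` or `N` in either row are excluded; no CpG masking or
correction anywhere). Transitions are A↔G and C↔T; everything else is a
transversion. The Kimura 2-parameter distance is
K = −½ ln(1−2P−Q) − ¼ ln(1−2Q); copies at or beyond saturation
(1−2P−Q ≤ 0 or 1−2Q ≤ 0) are flagged and excluded from age summaries
rather than dated.

Ages use T = K/μ with μ = 0.0116 substitutions/site/My: divergence from the
ancestral consensus accrues on the copy lineage alone, and K = 0.5 — the
repeat landscape's customary 50% limit — maps to ~43 My, the age scale of
the oldest insertions in this system. The divisor is configurable
(`divisor=2` halves all ages) for comparison with pairwise-distance
conventions.

The default copy-to-consensus comparison is *located-ungapped*: the copy is
anchored on the consensus by an infix edit-distance search (edlib), then
the exact offset is refined within ±8 bp by minimising mismatches, and the
two sequences are compared positionally. Edit-distance alignments trade
runs of mismatches for indel pairs, which deflates substitution counts by
~20% at K ≈ 0.3; the ungapped comparison is exact for colinear fragments
(terminal truncation, point substitutions), which is what both the
simulator and RepeatMasker-style fragment annotations produce. A gapped
mode (`alignment="gapped"`) is available for fragments carrying genuine
internal indels, and externally supplied aligned pairs can be scored
directly through `count_substitutions`.

## Fragment turnover

Each LINE/PLE fragment maps to its best library consensus: maximal percent
identity, ties to the longer alignment, then the lexicographically smaller
family name; hits below 60% identity are reported unmapped (within-genome
copies essentially never diverge that far). Hits may instead be supplied
as 12-column BLAST tabular files; the same top-hit rule applies. Truncation
classes use a 20-bp absolute tolerance at each consensus end — absolute
rather than relative, because a relative tolerance is vacuous on SINE-scale
consensuses. A fragment reaching only the 5′ end is 3′-truncated (the
genomic-deletion signature); only the 3′ end, 5′-truncated (RT
dissociation/RNase decay); both ends, full; neither, internal. Turnover
proportions are computed over the two truncated classes only, with full and
internal counted separately, and the overall percent 3′-truncated is
Σ five_prime_type / Σ(both truncated classes) × 100.

## Intact elements

ORFs come from a six-frame scan: from a start codon (or the frame start
when starts are not required) to the next in-frame stop, with lengths in
amino acids excluding the stop. Intactness gates are strict: a LINE must be
longer than 2700 bp with an ORF longer than 600 aa carrying start, stop and
an RT domain; a PLE longer than 2400 bp (full-length PLEs are ~2.5 kb) with
an ORF longer than 200 aa carrying both RT and GIY-YIG. Domain evidence is
consumed as tabular hits with an e-value gate of 0.01, and the domain must
fall within a qualifying ORF (the stricter reading). The tabular interface
means no live conserved-domain search is needed to build or test; calls are
monotone in the hit set — adding domain evidence can never turn an intact
call into not-intact.

## Deletion rates

A maximal gap run in one ingroup row of a three-way ortholog block is a
species-specific deletion when the outgroup and the other ingroup are each
at least 90% non-gap over those columns (the witness rule, which also
tolerates scattered Ns) and no gap run of the other ingroup overlaps it
(shared gaps are ancestral or alignment artefacts, not species-specific).
Size classes are micro ≤ 29 nt and mid-size 30–10,000 nt inclusive; the
two stated boundary conventions conflict at exactly 30 nt, and 30 is placed
in the mid class here (configurable). Runs above 10 kb are tallied
separately and not rated. The loss rate divides the normalised deleted
nucleotide count (del_nt per 10 kb of total aligned block length) by the
My since divergence (default 8.3 My, the monarch–*D. chrysippus* split).

## Gene flanks and gene sets

Flank profiles count TE bp and copies within 20 kb either side of the gene
body, gene body excluded by default (isolating flank signal; a switch
includes it to mimic a plain window search), flanks truncated at chromosome
ends, and coverage normalised by the flank bp actually available. The
immune-vs-other comparison defaults to per-gene observations (larger n,
more power) with a `by_type` option that averages within gene-type labels
first — the observational unit is recorded in the result, since group-level
means give a much smaller Welch df. Kruskal–Wallis uses tie correction with
df = groups − 1; post-hoc pairwise contrasts are rank-sum tests with
Benjamini–Hochberg adjustment. Single-gene enrichment labels a gene by its
flank TE copy number against the 2.5%/97.5% AUC cutoffs over all genes.

## The simulator

The generators are deterministic under a seed and return complete ground
truth. Defaults encode the standard study conditions:

- **Genome**: 10 chromosomes × 25 Mb (2,500 windows of 100 kb, the scale of
  a chromosome-level lepidopteran assembly). Background sequence is i.i.d.
  uniform over {A,C,G,T} — adequate because no stage models background
  composition.
- **Density**: per-window target TE density is gamma distributed with mean
  6.1 and SD 4.1 kb/100 kb — the observed between-window moments in this
  system — giving the continuous, right-skewed density distribution the
  AUC caller needs to be well-posed. An isolated spike far beyond a
  zero-width background cannot sit above a 99% cumulative-AUC cutoff (the
  polynomial smooths a few windows' mass into a lobe holding more than 1%
  of the area), so planted hotspots are a realistic tail, not a delta.
  Five hotspot windows are planted at 36.6 kb/100 kb (6× the mean), clear
  of the baseline tail.
- **Copies**: each copy is its consensus mutated to a target K2P value by
  solving for transition/transversion site fractions (p, q) with p/q equal
  to the ts:tv odds (default 2) and K2P(p, q) = K, then applying
  independent per-site substitutions — so the realised substitution
  pattern, not a rate process, targets K directly. Substitutions only by
  default: copies remain colinear consensus slices, so dating and
  truncation classes are exactly recoverable; an indel mode exists but
  defaults off. Truncation (equal quarters full / 5′-type / 3′-type /
  internal by default) removes consensus-terminal sequence before
  planting: 5′-type copies lose a uniform 10–70% suffix, 3′-type a prefix,
  internal 10–35% from each end.
- **Genes**: evenly spaced non-overlapping models (default 200 genes,
  8-kb spans, 4 exons) with 10% tagged immune plus an immune sub-type;
  flank planting gives immune flanks 3× the baseline density with Poisson
  copy counts.
- **Trios**: ~10-kb aligned blocks; each ingroup row carries planted
  deletions totalling 176.5 nt/10 kb in expectation, micro and mid-size
  nucleotides in equal parts (micro uniform 1–29 nt, mid uniform
  30–300 nt), placed in disjoint alternating slots so runs are never
  shared between species and always witnessed by intact rows.

What the simulator does **not** emulate: nested TEs, CpG hypermutation,
compositional heterogeneity, recombination, alignment error in the trio
blocks, and real consensus-library redundancy. Passing recovery tests
therefore demonstrate that each analysis stage is correct on clean,
colinear input at realistic sizes — not that the pipeline is robust to
assembly artefacts or mis-curated libraries.

## Problem sizes and numerics

The test suite and acceptance script run at sizes chosen to keep the whole
build reproducible on a laptop-class machine: 2,500 windows for hotspot
recall, ~1,000 five-kb copies for age recovery (≥ 300 per 1/5/25-My
group), 400 fragments for truncation recovery, 100 × 10 kb trio blocks for
deletion recovery, and 100 random fixtures for the exact tiling and
conservation checks. Polynomial fitting uses numpy's scaled-domain
`Polynomial.fit` for conditioning at degree 10; cumulative AUC uses
trapezoids on a 2,000-point grid (thresholds move by less than one coarse
grid step when the grid is refined 10×, which is tested). Degenerate
inputs — identical density values, zero-variance vectors, empty gene-set
complements, saturation — raise typed errors or set documented flags
rather than returning silent defaults.
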