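# Methods

This note documents the models and numerical choices behind
`karyoscope`: what each stage computes, the defaults and why, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Coordinates and windows

All internal coordinates are 0-based half-open. On disk, GFF3 and SAM
are 1-based per their standards; BED and BEDGRAPH are 0-based half-open.
A window grid tiles each scaffold with contiguous fixed-width windows;
the final window is truncated at the scaffold end (retained and
reported with its true length, never silently dropped). Defaults:
100 kb for coverage and density tracks, 500 kb for synteny painting,
100 kb slid by 1 kb for GC.

## Sex scan

**Model.** In an XX/XO system an X-linked scaffold has copy number 2 in
females and 1 in males, so its female:male depth ratio after
library-size normalization is 2 (log2 = 1); autosomes give 1 (log2 = 0).

**Coverage.** Every aligned reference base of every mapped record with
`MAPQ >= min_mapq` (default 0 — simulated reads carry no meaningful
mapping quality) is attributed to the window containing it; a read
spanning a window boundary contributes to both windows pro rata by
overlap. This makes base attribution exactly conservative: summed
attributed bases equal summed aligned bases, which the tests assert
with equality, not tolerance.

**Normalization.** Each sample is divided by its own median window
value, so each sample's median window becomes 1 and calls are invariant
to multiplying either library by any positive constant. The median is
used because X windows are a minority and should not drag the
baseline; a mean would be pulled by the X and by high-coverage repeat
windows. When more than half the windows are empty the median of
covered windows is used instead; an all-zero track is an error. One
consequence worth knowing: when the X makes up a large share of windows
(41% in the default toy genome), the male median lands on a lower-order
statistic of the autosomal depth distribution, biasing the normalized
ratio slightly below 2 (≈1% at toy scale). The calling band absorbs
this; analyses that need an unbiased point estimate of the ratio should
normalize by autosomal windows only, as `scripts/acceptance.py` does
with the double ratio (F_X/F_auto)/(M_X/M_auto).

**Ratio and masking.** Per window, log2(F) − log2(M) on normalized
depths, computed as a difference of logarithms so that swapping the
samples negates every unmasked value bit-exactly. Windows where either
sample's raw mean depth falls below `min_depth` (default 1.0×) or is
zero are masked, never fatal.

**Calling.** Per scaffold, the median of unmasked window log2 ratios
(numpy median; midpoint of the two central values for even counts).
X-linked if the median lies in [0.6, 1.4] — a generous band centered on
log2(2) = 1, wide enough for mapping noise but excluding autosomal
values; autosomal if in [−0.4, 0.4]; otherwise ambiguous, as is any
scaffold with fewer than half its windows unmasked. The source study
identified its X visually from the twofold gap, without a numeric rule;
these bands are this package's own, exposed as configuration. The
longest-first display order and the ">1 Mb" filter of the classic
coverage figure are plotting options only and never affect calling.

## Landscape

**GC.** (G+C)/(A+C+G+T) per window, case-insensitive; N and other
ambiguity codes are excluded from the denominator and an all-ambiguous
window reports NaN. Soft-masked lowercase bases count as their base
identity; repeat status comes only from the repeat annotation.

**Density.** Each feature is counted in exactly one window — the one
containing its start (anchor=midpoint available). Counting the start
rather than every overlap keeps totals conserved and is the documented
choice where per-window counting tools are ambiguous.

**Assembly summaries.** N50 is the standard smallest length L such that
scaffolds ≥ L sum to at least half the assembly; verified exhaustively
against a brute-force oracle for all small length multisets.
Completeness is 100·found/total single-copy ortholog groups, reported
as nearest-integer percent with full precision alongside (854 of 982 →
87%).

**Tandem clusters.** A left-to-right sweep per scaffold joins a gene to
the open cluster when the gap between its start and the rightmost end
seen so far is ≤ `max_gap` (overlaps count as gap 0). Tracking the
running maximum end makes the sweep exactly the transitive closure of
the pairwise gap relation, including nested genes — property-tested
against a connected-components oracle. Defaults `max_gap` 10 kb,
`min_size` 3: a deliberately conservative reading of "cluster" for
locally expanded gene families, exposed as flags.

## Macrosynteny painting

Each one-to-one ortholog is assigned to the 500-kb window containing
its focal gene start (the same anchor rule as the density tracks); the
window's fraction per reference chromosome is count/total over
orthologs in that window. Zero-ortholog windows are flagged
`no_synteny` rather than given fractions. The window's dominant label
is the argmax fraction among labels reaching `min_window_fraction`
(default 0.5); ties break deterministically by the canonical
karyotype order I, II, III, IV, V, X, then alphabetically. Per
scaffold, each reference chromosome's span is the summed length of the
windows it dominates; `fusion_flag` is set when ≥ 2 chromosomes each
span ≥ `min_span_bp` (default 1 Mb). The qualitative statements the
thresholds operationalize ("primarily homologous", Mb-scale spans) come
with no published numeric rule, so both thresholds are configuration.
Breakpoints are estimated as the boundary where the dominant label
changes between consecutive informative windows. Reciprocal painting
(reference windows painted by focal scaffolds) needs no separate code
path: swap the table's columns and re-run.

## Synthetic data generator

The generator's defaults define the conditions every recovery test and
the acceptance script run under.

* **Genome.** Five scaffolds: 3.5 Mb (X), 2.0, 1.5, 1.0, 0.6 Mb —
  sized so the full pipeline runs in seconds. The X is 3.5 Mb so the
  planted fusion breakpoint at 4/7 of its length (II:IV segment ratio
  4:3, i.e. 10:7.5) falls exactly on a 500-kb window boundary and both
  fused segments comfortably exceed the 1-Mb span threshold, making
  fusion recovery stable across seeds at the default thresholds.
* **Sequence.** Bases drawn independently with per-position GC
  probability `gc_arms` in the outer `arm_fraction` (default 25%) of
  each end and `gc_center` elsewhere; G vs C and A vs T equiprobable.
  Defaults sit near 45–47% GC with arms a few points above centers.
* **Repeats.** Poisson process per region, arms at 3–5× the central
  rate (X: 25 vs 5 per 100 kb) — the arms-vs-center contrast
  characteristic of nematode chromosomes, which the repeat-density
  track must recover.
* **Genes.** Uniform placement at 350 per Mb (matching the ~366/Mb of a
  ~31k-gene, ~85-Mb nematode genome), lengths 0.5–3 kb; plus two
  planted tandem clusters of five same-family genes with 1.5-kb gaps,
  recorded as ground truth for cluster detection.
* **Reads.** Single-end fixed-length placements, uniform starts,
  Poisson per-scaffold counts with expectation
  `copy_number × depth × L / (2 × read_length)` — copy number 2 except
  the X in XO males (1), so realized per-base depth equals `depth` at
  copy number 2 and half that on the male X. Default 20×, 100 bp. No
  quality strings, no sequencing errors, no pairing: coverage analysis
  needs only positions. The male is modeled XO (no Y); the twofold
  logic is identical under XY with a non-recombining Y, but no Y
  sequence is simulated.
* **Orthologs.** Positions uniform per scaffold (default 80 per Mb,
  roughly the one-to-one ortholog density of related nematode pairs);
  each pair's reference chromosome follows the planted fusion map of
  its position; a dropout fraction (default 10%) is removed at random.
  Gene ids are unique on both sides by construction.

Everything is deterministic given the configuration and seed; the
fixture bundle (FASTA/GFF3/BED/SAM/TSV plus a truth TSV) round-trips
through the package's own readers byte-for-byte reproducibly.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: mappability and GC bias in coverage,
paralog cross-mapping, heterozygosity, sequencing error, collinear gene
order within synteny blocks (positions are exchangeable within a
segment), repeat-driven misassembly, and partially X-linked
(pseudoautosomal) regions. Tests demonstrate that the statistics
recover planted truth under their own sampling model, not robustness to
those artifacts.

## Numerical and interface choices

* Sliding-window GC uses prefix sums; brute-force per-window scans are
  kept as test oracles only.
* The simulation fast path (`coverage_from_placements`) and the SAM
  path (`coverage_from_alignments`) implement the same attribution rule
  and are cross-checked for equality in tests.
* Problem sizes in tests and the acceptance script follow the toy
  defaults above: 20× (calling demonstration) and 10× (20-seed recovery
  sweep) depth, 20 orthologs per Mb at 50% dropout for the 20-seed
  fusion sweep — deliberately harsher than the generator defaults to
  show recovery is not fragile.
* Pipeline outputs are TSVs with `#` headers carrying version, config
  hash and seed; no timestamps, so reruns are byte-identical. Failed
  stages leave `.partial` files; completed stages rename atomically.

## Limitations

The sex scan assumes a homogametic/heterogametic depth contrast and
cannot separate X from Z systems by itself (a ZW female would show the
inverse signature). Copy-number segmentation, GC-bias correction and
Y/W detection are out of scope. Painting is macrosynteny only — it
ignores gene order, so it detects fusions and translocations at window
resolution but not inversions. Threshold defaults are tuned for
chromosome-scale scaffolds; heavily fragmented assemblies will land in
`ambiguous`/sub-threshold territory by design.
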