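# Methods

## Data model and coordinate conventions

All statistics operate on a `BinnedGenome`: fixed-width, half-open, 0-based
bins (default 50 kb) tiling each chromosome, the last bin of a chromosome
possibly short. Chromosome naming dialects (`1` vs `chr1`) are normalized
to the `chr`-prefixed form. Mitochondrial and unplaced contigs are always
dropped; chrX/chrY are dropped by default (`exclude_sex_chroms=False` keeps
them) because sex chromosomes confound compartment comparisons across cell
types of different karyotype and are conventionally excluded from
subcompartment panels.

Juicer text dumps (`pos1 pos2 value`) are read with positions interpreted
as bin start coordinates, chromosome-local, at the declared resolution —
this is the dump dialect and removes off-by-one ambiguity. Contact maps
store the canonical (min, max) key once and answer symmetric queries; intra
maps may contain only same-chromosome pairs and inter maps only
cross-chromosome pairs, which is enforced at construction and makes the
"other chromosomes only" restriction of the A/B ratio structural rather
than a per-query filter.

**Balancing failures.** A NaN (or negative) dump entry is dropped from
storage; a bin is routed to the invalid mask iff it has at least one
dropped entry and no finite entry. This matches how Knight–Ruiz failure
manifests — a bad row is NaN against every partner — while a good bin that
merely touches a bad one keeps its finite entries. Masked bins contribute
to no numerator and no denominator anywhere downstream.

**Label assignment.** Subcompartment BED intervals (raw Calder labels
renamed through the fixed map A.1.1→A1 … B.2.2→B4) are projected onto bins
by maximal overlap, accumulated **per label** rather than per interval, so
assignment is invariant under splitting an annotation into adjacent
same-label pieces. Exact ties go to the label whose interval appears first
in sorted genomic order (deterministic, logged). Uncovered bins are NA, and
NA bins are excluded from both numerator and denominator of every
proportion — the alternative (counting NA-in-one-cell-type bins as
repositioned) would inflate repositioning by the NA fraction.

## Interchromosomal A/B ratio

For bin *i*, `A_i` and `B_i` sum its cross-chromosome balanced contacts
with compartment-A and compartment-B bins; per subcompartment,
`ratio = (ΣA_i/N_A) / (ΣB_i/N_B)`. `N_A`/`N_B` are measured in bins —
equivalent to length at one resolution, and the ratio is invariant to the
unit. A bin's partners count regardless of the bin's own label (no
self-compartment exclusion). The ratio is flagged NaN (never ∞) when
`C_B = 0`. Per-bin ratios `(A_i/N_A)/(B_i/N_B)` (bins with `B_i = 0`
dropped) are available for violin-style distributions next to the
aggregate; whether published violin panels show per-bin values or bootstrap
replicates is not documented, so the per-bin reading is exposed explicitly
as an assumption.

The ratio is invariant under global rescaling of the map, and swapping the
A/B roles maps every ratio to its reciprocal; both are tested, along with
brute-force triple-loop agreement at 1e-12 relative tolerance on ≤ 50-bin
instances.

## Contact-domain strength

The background `B_l` is the mean balanced contact of locus pairs at bin
distance `l` with both endpoints in the same contiguous B-compartment
block. Blocks are half-open, so the pair count at distance `l` is
`Σ_b max(0, len_b − l)` — this makes `count(l=0) = Σ len_b`, consistent
with including the diagonal in the strength sum (the printed closed-form
would be ambiguous by one under closed intervals). Diagonal pairs (`i = j`)
are included by default in both `B_0` and the domain sum; balanced
diagonals are sometimes unreliable, so `include_diagonal=False` switches
both off coherently.

A domain spanning bins X..Y scores
`S = Σ_{i≤j} (I_{i,j} − B_{j−i}) / T`. Pairs touching a masked bin are
dropped from both the numerator and `T` (default); a flag instead keeps
them in `T`, treating missing contacts as exactly background-level. For
distances where `B_l` is undefined (longer than every B block, or zero
unmasked pairs) the background is extended by a power-law fit
`log B_l ~ a + b log l` over the defined range, falling back to the nearest
defined value when fewer than two positive points exist; the fraction of
pairs whose background was extrapolated is reported with every score, so a
result resting mostly on extrapolation is visible.

Domains called at 5 kb and 10 kb are merged by the keep-smaller rule: the
union is taken and any call overlapping (≥ 1 bp) a strictly smaller
cross-resolution call is dropped; identical intervals collapse to the finer
record. Two equal-span overlapping cross-resolution calls both survive
(the rule gives no reason to prefer either). Domains are scored on the
matrix at whatever resolution it is supplied — the formulas are
resolution-generic — with the compartment mask projected from the labeling
resolution when they differ. Each domain is assigned the subcompartment of
maximal bp overlap (ties to the earlier label in rank order A1..B4), and
optionally a common-A1/variable-A1 class by the same rule. A size filter
(e.g. the 160–220 kb stratum) is available for robustness checks but is
not a default.

## Transitions, persistence, region classes

Transition tables count bins non-NA in both cell types; the repositioning
proportion is 1 − trace/total, optionally restricted to source rows or
computed under the 4-class merge {A1}, {A2,A3,A4}, {B1,B2,B3}, {B4}
(hard-coded; merging can only move off-diagonal mass onto the diagonal, so
the merged proportion never exceeds the 8-state one — a tested law).
Persistence of a target state is reported against a **named reference cell
type** (a required argument, not a default): persistent bins carry the
state in every panel member, and the proportion divides by the reference's
state bins. Since {A1} is a singleton class under the merge, A1 persistence
is identical under both schemes. Region classes: common A1 = A1 everywhere;
variable A1 (per cell type) = that cell type's A1 minus common A1 (an exact
partition, tested bin-wise); common B4 analogous. Gene-density
denominators use each cell type's own region lengths, not the reference's.

## Gene classes and positioning statistics

Thresholds: active FPKM > 1, highly expressed FPKM > 10. Cell
type-specific in c: FPKM_c > 1 and FPKM_c / max(FPKM_other, ε) ≥ 5 with
ε = 0.01 guarding zeros — the "five-fold versus the others" wording is read
as versus **each** other cell type (the strictest consistent reading;
versus-max is mathematically the same and versus-mean is available behind a
flag). Genes are located by TSS (annotated start on +, annotated end on −),
not gene-body overlap. log2 transforms use pseudocount 1. The up/down
threshold of the expression-change grid is |log2 fold| ≥ 1 (configurable;
unstated in the figure it mirrors). Each (src, dst) cell's up/down split is
Fisher-tested against the pooled split of all genes, and grids/batches are
Benjamini–Hochberg adjusted (the source material reports raw significance
tiers; both are emitted). Enrichment contrasts default to cell
type-specific vs housekeeping genes across variable vs common A1, with the
full 2×2 table recorded in every result; the odds ratio is the raw
cross-product with no continuity correction, flagged NaN on a zero cell.

Gap lengths are differences between consecutive sorted TSS within one
merged region interval — never across interval breaks. Boundary metagene
profiles are orientation-agnostic: TSS are counted in 50 kb offset bins
over ±500 kb windows (both configurable) centered on deduplicated TAD or
domain boundary coordinates, normalized as mean TSS per offset bin per
contributing boundary; offset bins extending beyond a chromosome end are
excluded from that boundary's average, with per-offset denominators
reported (the published y-axis normalization is not numerically described,
so real-data curve shapes should be compared qualitatively).

## Synthetic data generator

The generator emulates the statistical structure the statistics assume;
its defaults are the study conditions, chosen once:

- **Genome**: 3 × 20 Mb at 50 kb (1200 bins), five cell types — small
  enough that the entire pipeline and test suite run in minutes while each
  state still holds >100 bins.
- **Labelings**: geometric blocks (mean 6 bins ≈ 300 kb, the scale of
  Calder annotations) labeled by target fractions with A1 and B4 largest
  (0.15 each). A pinned subset of the reference cell type's A1 bins — the
  configured fraction 0.3253, matching the reported A1 persistence level,
  and 0.2895 for B4 — stays put in every cell type; every other bin
  relabels per non-reference cell type with probability 0.6 (yielding the
  observed ~55–60% pairwise repositioning) under a rank-neighbouring
  kernel `exp(−|Δrank|/τ)`, τ = 1. Accidentally persistent non-pinned bins
  are nudged in one random cell type so the planted common fraction is
  recovered *exactly*. 2% of non-pinned bins per non-reference cell type
  are NA, emulating unannotated Calder output.
- **Intra maps**: Poisson samples of
  `λ = depth · (1+d)^{−α} · a_i a_j` with α = 1 (the classic contact-decay
  exponent), depth 100, and strictly ordered per-rank affinities spanning
  a(A1)/a(B4) = 4. Intensities are treated as already-balanced values:
  the downstream formulas consume balanced contacts and re-implementing KR
  balancing is out of scope.
- **Planted domains**: 100 non-overlapping spans of 3–8 bins inside
  compartment-A runs; their pair intensities are overridden to
  `E[B_l] + e` (exact expected B background at that distance plus the
  enrichment, e = 10). Because both the background estimator and the
  strength sum are linear in Poisson counts, the expected recovered
  strength of a planted domain is exactly e — making the 5%-bias recovery
  check meaningful. Planting in A territory keeps the B background
  uncontaminated. Domain sizes are capped below the longest B block so no
  planted pair needs background extrapolation.
- **Inter maps**: Poisson samples of
  `λ = depth_inter · exp(−|rank_i − rank_j|/τ)`, τ = 3. A pure product
  model `a_i a_j` would make the A/B ratio identical for every
  subcompartment (the query bin's factor cancels between numerator and
  denominator), so a similarity kernel is required to produce the graded
  A1→B4 ratio the statistic is designed to detect.
- **Genes**: gradient genes placed per bin at densities 18/Mb (common A1),
  9/Mb (variable A1) down to 1/Mb (B4) — a planted 2-fold common/variable
  contrast — with log-normal FPKM whose median follows the bin's state
  *in each cell type* (8.0 → 0.3, σ = 0.5 on the log scale), so
  expression-by-state and expression-change-by-transition statistics have
  real signal. Housekeeping genes (60 by default, genome-scaled) are high
  (median 30) everywhere and split across common/variable A1 by territory
  length; each cell type-specific gene (25 per cell type by default) is
  high in exactly one cell type and placed in variable-vs-common A1 at the
  configured odds multiplier (3.0) over the length odds, which makes the
  specific-vs-housekeeping Fisher OR equal the multiplier in expectation.
  Recovery studies that need more power state their own gene counts
  (e.g. 2000 specific genes for the odds-ratio check).
- **Signal**: per-bin Gaussian noise (σ 0.3) around strictly monotone
  per-rank means — H3K27ac and Nipbl decreasing, H3K9me3 increasing.

One `numpy.random.Generator` drives everything; a fixed seed reproduces
the dataset, all written files and every downstream statistic
byte-for-byte.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: KR balancing artifacts beyond simple masked bins,
genomic distance-dependent noise structure (Poisson only), TAD/loop
fine structure within domains, chromosome-territory effects in inter maps,
copy-number and mappability biases, and realistic gene length/isoform
structure (genes are TSS points). The measured *active*-gene density
contrast between common and variable A1 is also diluted below the planted
2-fold gradient by the housekeeping and specific genes placed in both —
ordering claims are tested, absolute folds are not.

## Problem sizes and numerical choices

Oracle-equivalence checks run on ≤ 50-bin instances at 1e-12 relative
tolerance (the computations are sums and ratios of doubles; tighter would
test rounding order, looser would hide indexing errors). Recovery checks
use the default 1200-bin genome with fixed seeds: 100 planted domains for
the 5%-bias bound, the 2000-specific-gene condition for the odds-ratio
window [2.4, 3.75], and 200 replicates for the null calibration of the
expression-change grid, whose empirical significant-cell rate must not
exceed the upper binomial bound of 5% (Fisher's exact test is conservative,
so the observed rate sits near 1%). Background extrapolation uses a
power-law fit because contact decay is approximately power-law; the
nearest-defined fallback only triggers on degenerate fixtures.

## Known limitations

- Real-data headline values depend on external datasets addressed by
  accession; the package validates methodology on planted ground truth and
  leaves real-data integration to the user (`a1scape run` on their files).
- The cooler adapter (`ContactMap.from_cooler`) is a convenience lazy
  import and is not exercised by the test suite; text dumps are the
  first-class interchange format.
- `merge_domain_calls` is quadratic per chromosome pair-check; fine for
  Arrowhead-scale call sets (thousands), not for millions of intervals.
- The expression-change background includes the tested cell's own genes
  (pooled background); for grids dominated by one huge cell this makes the
  test slightly conservative.
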