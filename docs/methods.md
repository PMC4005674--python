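# Methods

This note records the statistical model behind `fourc`, the parameters
that matter, the design choices made where the design was genuinely open,
what the synthetic-data generator does and does not emulate, and known
limitations.

## The unit of analysis

4C-Seq resolves contacts at the level of 3C fragments: intervals between
consecutive cut sites of the primary restriction enzyme. `fourc` digests
the genome in silico (IUPAC-degenerate site matching; palindromic sites
matched on one strand, non-palindromic sites additionally via the
reverse complement with the cut offset mapped back; `N` bases in the
genome never match, so unplaced sequence cannot create phantom sites) and
tiles each chromosome exactly: fragment *i* ends where fragment *i*+1
starts. Coordinates are 0-based, half-open everywhere, including all
emitted files.

Not every fragment is observable. An end of a fragment is *capturable*
when the distance *d* from the primary-site boundary to the nearest
secondary-enzyme cut strictly inside the fragment satisfies
*d* ≥ `min_map_length` (default 20 bases — the shortest captured stretch
that can still be aligned, given typical read lengths) and
`size_min` ≤ *d* + `primer_length` ≤ `size_max` (the size-selection
bounds of the sequencing library; `primer_length` is the user-supplied
effective constant covering primers plus adapters). A fragment is
mappable iff either end is capturable; "blind" fragments without an
internal secondary site, and fragments shorter than `min_map_length`,
are unmappable. This amplicon-length rule is this package's concrete
parameterization of the library-design constraints; it deliberately
exposes every quantity a 4C design names (enzymes, read length, primer
length, size selection). A linearization enzyme, when supplied, is
annotated but never excludes fragments, since its effect is
viewpoint-specific. Unmappable fragments keep their rows (and any reads)
in the on-disk tables but take no part in any statistic: windows slide
over mappable fragments only, and the shuffle pool is the mappable set.
Alignment-uniqueness mappability (k-mer self-alignment of the genome) is
out of scope; reads are instead filtered by mapping quality
(`min_mapq` default 1).

Read assignment is by containment of the 5'-most aligned base (strand
aware: reference start for forward, alignment end − 1 for reverse). An
optional `boundary` mode additionally requires that base to lie within
`boundary_tolerance` (default 4 bases, the length of the random barcode
stretch in a typical 4C primer design) of the fragment boundary on the
side matching the read strand, since genuine 4C reads begin at a
restriction junction.

## The significance threshold

The null hypothesis is exchangeability of counts across mappable
fragments. For window size *W* (fragments), each permutation *p*
randomizes the counts and yields

X_p = min { c ≥ 1 : |{shuffled window sums ≥ c}| / |{observed window sums ≥ c}| < α },

with the convention that the ratio is 0 when the denominator is 0 (so a
valid cutoff always exists, bounded by max(observed) + 1 and
max(shuffled) + 1). The per-chromosome threshold is the order statistic
T = X_(r) of the ascending-sorted cutoffs with
r = P − ⌊P·k/100⌋ + 1, clamped to [1, P] — the smallest X within the top
k percent, an attained value with no interpolation, computed over all P
values (not unique ones). Defaults: α = 0.01, P = 1000, k = 5, W = 5.
Significance is inclusive (sum ≥ T), since X is defined as the minimum
count a window needs. The FDR estimator itself (shuffled tail over
observed tail, per permutation) is this package's declared estimator; it
is the standard empirical-FDR form and is frozen in the test suite
against a brute-force enumeration oracle.

Two shuffle units are offered, and the choice matters:

* `vector` (default): a uniformly random permutation of the per-fragment
  count vector. The multiset of counts — including extreme
  single-fragment values — is preserved exactly, which makes the null
  faithful to overdispersed data and the caller conservative: an isolated
  single-fragment spike is exactly as extreme in every shuffle as in the
  observed data and therefore essentially never significant on its own.
  A corollary: at W = 1 the observed and shuffled sums are the same
  multiset, every X equals max(observed) + 1, and nothing is ever called.
* `read`: every read is re-placed independently and uniformly on a
  mappable fragment. This matches the picture of scattering reads over
  fragments, gives single-fragment events a chance to reach
  significance (hence meaningful W = 1 analyses), but understates the
  variance of a heavily overdispersed background and is accordingly more
  liberal.

Calibration (test suite): on exchangeable negative-binomial null
chromosomes (2000 fragments, μ = 2, r = 0.3, W = 5, α = 0.01, P = 200),
the fraction of simulations yielding any significant window is a few
percent under the vector null.

The `pooled_mean` comparator mode averages the shuffled tail counts over
all permutations first and solves for a single cutoff. On data with
genuine peaks above the shuffled range, that crossing happens deep in the
shuffled tail, where the average is moved by the magnitude of rare
extreme permutations; the percentile order statistic responds only to
their count. At the recommended permutation depth the percentile
threshold is therefore the more stable of the two on heavy-tailed data —
the motivation for the default. On smooth regimes (read-scattering null,
or backgrounds without peaks) the two are comparable and the pooled mean
can even be the steadier; the comparison test pins the heavy-tailed,
peak-bearing regime where the distinction matters.

Per-permutation RNG streams derive from (seed, CRC32(chromosome),
permutation index), so results are bit-reproducible and independent of
evaluation order; chromosomes can be processed in parallel without
changing any number.

## Masking and localized backgrounds

Fragments overlapping a mask region (by any base) are removed whole from
the analysis set — observed windows and shuffle pool alike. Mask-out
(e.g. the viewpoint-proximal zone, whose counts can exceed distal ones by
orders of magnitude and would otherwise inflate the chromosome-wide
threshold) and region restriction (a localized background model for one
locus) are duals: restricting to a region equals masking out its
complement, exactly so when regions are aligned to fragment boundaries
(a fragment straddling a region edge is removed by mask-out but retained
by restriction to the base-level complement — the whole-fragment overlap
rule is deliberate and documented rather than split).

## Interactions and prioritization

Contiguous significant windows (consecutive window indices — ranges that
overlap or abut) merge into one interaction; read-free fragments are
trimmed from both ends (interior zeros are kept); the reported read total
is the sum over retained fragments, so span and mass agree. Member
windows are graded Broad / Intermediate / Narrow as in the README; ties
for the most abundant fragment resolve to the leftmost position (the
Broad test is tie-invariant; only the Intermediate neighbor set can
differ), the neighbor replacement is the real-valued mean of the 1 or 2
in-window flanking fragments (0 when W = 1, which is why every W = 1 call
is Narrow — a chromosome-wide neighbor rule would contradict that), and
the comparison stays ≥ T. An interaction takes its broadest member grade.
Replicate intersection requires exact fragment identity on a shared map
and retains the broadest grade per shared fragment; per-replicate unique
fragments and pairwise overlap counts are reported alongside.

Grades describe dependence on a single fragment, not truth: a genuinely
reproducible contact sitting on one large fragment (little flanking
sequence to capture) can be Narrow, and a background outlier adjacent to
an artifact can lift a window to Intermediate legitimately.

## The synthetic-data generator

`simdata` emulates the features the caller's statistics depend on:

* fragment lengths geometric with mean 4000 bases (a 6-cutter-like map)
  and 20% of fragments unmappable at random — a realistic blind-fragment
  share for a HindIII/NlaIII-style design;
* exchangeable negative-binomial background on mappable fragments,
  defaults μ = 2, r = 0.3 (variance μ + μ²/r ≈ 15 — Poisson would
  understate window-sum variance and make permutation thresholds
  unrealistically tight);
* viewpoint distance decay: independent Poisson draws with mean
  s·(1 + d)^−γ at ordinal distance d, added to mappable fragments —
  added as draws, not deterministic inflation, so the null remains a
  counting process and shuffle-based calibration stays meaningful;
* planted interactions: exactly N reads multinomially distributed over
  mappable fragments under a discretized Gaussian kernel of width σ
  fragments, truncated at 4σ (σ = 0 puts all N on the center fragment).
  The default planted strength in the recovery experiments, 200 reads
  (20× the mean null window sum at W = 5), represents a clear,
  frequently-captured contact.

It does not emulate sequence-level artifacts (ligation biophysics,
PCR-duplicate structure, fragment-specific capture efficiency, genome
mappability structure), so passing recovery tests demonstrate the
statistics, not robustness to those real-data effects.

Experiment scales in the shipped tests and acceptance script (chosen as
the package's study sizes): 200 null simulations of 2000 fragments at
P = 200 for calibration; 100 simulations per planted-peak arm (broad
spread-3 peaks under the vector null; spread-0 spikes, whose
classification is read off the rare detections the conservative null
allows); window-size trends on 4000-fragment chromosomes with a
strength continuum of 36 planted events (strong spread-2..4 interactions
interleaved with weak single-fragment events that dilute below threshold
as W grows) under the read null, where window-size effects express as in
real analyses; the threshold-variance comparison on one heavy-tailed
peak-bearing fixture at P = 1000 with 20 runs per mode in each of 20
trials.

## Numerical and degenerate-input choices

* Cutoff search is exact over the candidate set {1} ∪ {v + 1} for
  attained values v (tail counts are constant between attained values);
  the brute-force enumeration over all integers is kept as a test oracle.
* Empty window vectors (W exceeding the mappable-fragment count) yield
  the vacuous cutoff X = 1 with a warning; a chromosome with no mappable
  fragments after masking is an error naming the chromosome.
* retab parsing is strict: negative counts, non-integer fields, missing
  columns, or non-tiling rows raise errors naming the line number.
* Artifacts are written atomically (temp file + rename); identical
  configuration and seed reproduce byte-identical files; every artifact
  header echoes its configuration and seed.

## Limitations

* No analytic null; thresholds require permutations (P = 1000 on a
  2000-fragment chromosome takes on the order of a second per
  chromosome).
* One threshold per chromosome; position-dependent thresholds are
  approximated by combining masked and restricted runs.
* Allele labels on count tables are opaque pass-through metadata;
  SNP-aware read splitting and allele-specific significance are outside
  the package's scope, as are alignment and FASTQ processing.
* The barcode-duplication statistic reports per-fragment duplicate
  fractions; duplicate reads are reported, not removed, by default — an
  opt-in flag collapses identical (fragment, barcode-pair) reads to one.
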