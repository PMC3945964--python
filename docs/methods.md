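# Methods

## Distance model

All divergence statistics use the Kimura two-parameter distance
*d* = −½ ln[(1 − 2P − Q) √(1 − 2Q)], where P and Q are the transition
(A↔G, C↔T) and transversion proportions over the sites comparable in a
pair. Sites where either sequence carries a gap or an IUPAC ambiguity code
are removed pair by pair (pairwise deletion); complete deletion would
discard most columns of length-variable markers such as ITS2. No gamma
rate-heterogeneity correction is applied. When divergence saturates
(1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0) the logarithm is undefined; such pairs are
flagged, excluded from means/minima/maxima with a logged count, treated as
infinitely distant by the identification rules, and imputed as the largest
defined distance when a tree must be built over them. Treating ambiguity
codes as deleted rather than partially matched can shift statistics in the
last digit relative to tools that score partial matches.

## Dataset preparation

Records shorter than a per-marker ungapped-length floor are removed before
analysis: COI < 450, 16S < 350, 12S < 240 bases; ITS2 records covering
less than 70% of a dataset-level full length. Length is counted excluding
alignment gaps, since gaps are artifacts of alignment, not sequence. The
ITS2 full length must be supplied; a helper defaults it to the longest
ungapped record in the dataset, which is what the CLI uses when the flag is
omitted (whether "full length" should be global or per-species is genuinely
open; a global constant is the simplest defensible choice and is exposed as
a parameter). Alignments are then trimmed to the region covered by every
record — from the latest first non-gap column to the earliest last non-gap
column — leaving internal gaps untouched; trimming refuses to proceed if
fewer than 50 columns would remain, which catches alignments of disjoint
fragments.

Three evaluation sets are derived: set 1, all records whose status is
published, locally amplified, or screened-in; set 2, the records of species
with at least two set-1 records, used as queries; set 3, set 1 without
subadult-derived amplified records and without screened-in records, used to
check whether distance overlaps are artifacts of those record classes.

## Divergence parameters

Six parameters summarize a marker, each reported as mean ± sd over its
grouping unit:

| parameter | unit | definition |
|---|---|---|
| average inter-specific distance | sequence pairs | pooled mean over all heterospecific congeneric pairs |
| θ′ (theta prime) | genera (≥ 2 species) | mean heterospecific congeneric distance per genus |
| minimum inter-specific distance | genera | smallest heterospecific congeneric pair distance per genus |
| average intra-specific distance | sequence pairs | pooled mean over all conspecific pairs (species with ≥ 2 records) |
| θ (theta) | species (≥ 2 records) | mean conspecific distance per species |
| coalescent depth | species | maximum conspecific distance per species |

The pooled/grouped duality is deliberate: θ and θ′ weight every species and
genus equally, removing unequal-sampling bias, while the pooled means weight
every pair equally. Gap histograms are built at species level — each
species' smallest distance to a heterospecific congener against its
coalescent depth — since the per-genus minimum hides which species collide.
The gap ratio (mean minimum inter-specific distance over mean depth) is
reported as a single separation index; it is undefined at zero mean depth.

## Threshold optimization

Candidate boundaries run from 0 to 15% on a grid (default step 0.01%, fine
enough to resolve optima quoted to two decimals). At threshold t, false
positives are conspecific pairs with d > t (the threshold would split a
species) and false negatives are heterospecific pairs with d ≤ t (it would
lump two species). Errors are counted over sequence pairs — the only
definition computable from a distance matrix alone. The optimum minimizes
FP + FN; ties resolve to the smallest threshold and the full tie set is
recorded. The boundary inequality (merge at exactly d = t or not) is a
configuration switch defaulting to merge.

## Identification rules

Queries are identified against a reference library with the query itself
removed (self-match exclusion — without it every rate is trivially ~100%
whenever queries are drawn from the library). A call is *correct* only when
the assigned binomial equals the true one after case/whitespace
normalization; uncertain calls and no-hits count as failures. Synonyms are
not resolved.

* **Nearest neighbour**: species of the minimum-distance reference; ties —
  exact after rounding to 10 decimals, so duplicated sequences tie reliably
  — across several species give an uncertain call; all-undefined rows give
  no-hit.
* **Best hit**: full Smith–Waterman with affine gaps (match +2, mismatch
  −3, gap open 5, gap extend 2 — the classic nucleotide-search scheme) and
  Karlin–Altschul statistics (λ = 0.625, K = 0.41, search space m·n).
  Hits need ≥ 80% identity over their aligned columns and E ≤ 10⁻⁶; up to
  100 are kept, ranked by bit score. A top score shared across species is
  uncertain. All parameters are overridable.
* **Liberal tree-based**: on a neighbour-joining tree of references plus
  queries, the query's attachment node has two directions away from the
  query; if one (or both, agreeing) contains reference leaves of a single
  species, that species is assigned — this reproduces both qualifying
  patterns ((X,X),Q) and ((X,Q),X) and is independent of where the tree is
  rooted. One tree is built for all queries (a per-query rebuild switch
  exists; rebuilding changes nothing on clean data and is quadratically
  slower).
* **Liberal tree-based + threshold**: as above, but a query whose nearest
  reference lies at or beyond the distance threshold becomes uncertain.
  The threshold defaults to the same run's boundary-scan optimum
  (self-calibration) and can be overridden with published per-marker values.

Trees come from an internal neighbour-joining implementation; negative
branch-length estimates are clamped to zero with the deficit moved to the
sibling branch, preserving path lengths through the joined node. The
implementation is cross-checked against an independent library NJ in the
test suite.

## Screening of unverified records

Records marked *unpublished* are admitted to the reference library only if,
on the midpoint-rooted NJ tree of the whole dataset, their smallest
ancestral clade containing any reliable record (published or amplified)
contains exclusively reliable records of their nominal species — other
unpublished records in that clade must also carry that name. Records of
species with no reliable representative are rejected with that reason.
Reliable records never change status. Midpoint rooting was chosen because
the clade criterion needs a rooted tree and midpoint is the standard
rooting for distance trees; the published criterion was formulated on
(rooted) Bayesian consensus trees, and only the clustering decision rule —
not the tree inference — is reimplemented here, without posterior-support
cutoffs.

## Statistical comparison

Marker and method effects on success rates are compared with Duncan's
multiple range test. Group means are sorted; a span of p consecutive means
is tested against the least significant range built from the studentized
range quantile at protection level 1 − (1 − α)^(p−1) (α = 0.05 by default)
and the pooled error variance; spans inside a non-significant span are
protected (declared non-significant), and maximal indistinguishable runs
share a letter. Unequal group sizes use the harmonic mean of the pair being
compared. The test refuses to run when every group has zero internal
variance. Replicate units default to per-genus success rates — the
replicate structure behind published method comparisons is never stated, so
this is the package's own choice, exposed as a parameter.

## Synthetic data generator

The generator emulates a curated tick-barcode library's statistical
structure: 4 genera × 5 species × 4 records of 600 aligned columns,
conspecific divergence targeted at 1.5% and congeneric heterospecific
divergence at 20% (within the ranges reported for real tick markers:
intra ~0.3–2%, inter ~13–42%), with a transition:transversion ratio κ = 4
typical of animal mitochondrial sequences. Sequences evolve by the exact
K2P site-substitution probabilities (multiple hits included) on a
star-within-star genealogy: root → genus ancestors → species centroids →
individuals. Branch lengths are set so the *expected pairwise K2P distance
between individuals* equals the stated targets — the centroid separation
discounts the two individual branches. Because the K2P estimator is the
inverse of the generating process, recovered distances are consistent with
branch lengths (verified by Monte-Carlo in the tests).

Optional complications: *overlap pairs* place two congeneric species
centroids 0.5% apart (the inseparable-species scenario); *deep splits* give
a species a second centroid four intra-divergences away, so
cross-subpopulation records sit near 5 × intra ≈ 7.5%, matching the rare
~9% deep intra-specific splits seen in real libraries; *mislabels* emit a
fraction of records under a wrong congeneric name with status unpublished,
which screening should reject. Given one seed the generator is bit-identical
across runs.

What the generator does **not** emulate — indels and alignment error, rate
heterogeneity across sites, coalescent genealogies within species,
selection, chimeric or low-quality sequences. Passing tests therefore show
the statistics and decision rules are implemented correctly and behave as
expected where divergence structure is the only signal; they do not show
robustness to alignment artifacts or misspecified substitution processes in
real data.

## Problem sizes and numerics

The default test and acceptance runs use the 4 × 5 × 4 × 600 design (80
records, 3 160 pairs), 20-seed screening replicates, and ≤ 10-record panels
for alignment-oracle comparisons — sizes at which every stage's result is
checkable by exhaustive enumeration while recovery statistics still have
enough replication for 3-standard-error bounds. Distance ties in nearest
neighbour are compared after rounding to 10 decimals; threshold grids are
rounded to 10 decimals to keep grid arithmetic exact; NJ join ties resolve
to the first row-major minimum for determinism.

## Known limitations

* Success is scored per sequence, not per species; rare species influence
  rates less than well-sampled ones.
* The best-hit search is exhaustive Smith–Waterman over the reference — an
  exact, self-contained analogue of a seeded database search; bit scores
  and E-values use fixed Karlin parameters rather than values fitted to the
  scoring scheme, so E-values are comparable within a run but not
  identical to an external search engine's.
* Screening inherits NJ topology errors near zero-length branches; records
  screened out for topology reasons are recoverable by inspecting the
  written screening report.
* The liberal tree rules examine only the query's attachment node; more
  distant monospecific structure (e.g. a query one node outside a large
  monospecific clade) is not credited.
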