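# Methods

This note documents the models, defaults, and numerical choices behind
`cinsig`, and what the synthetic-data tests do and do not establish.

## Coordinate model and inputs

All coordinates are 0-based half-open internally. SEG-style input (1-based
inclusive) is converted on read. The bundled genome model covers GRCh38
autosomes plus X with approximate centromere midpoints; arms are
p = [0, centromere) and q = [centromere, length). Segments must be
per-sample, per-chromosome sorted and non-overlapping; junctions are
breakend pairs stored canonically (A ≤ B by chromosome, then position) with
the orientation convention +/− deletion, −/+ duplication, ++/−− inversion,
cross-chromosome translocation. An explicit svtype column always overrides
orientation inference.

## Sample selection

Purity estimates whose caller solution range (max − min) exceeds 0.5 are
set to zero — strictly greater, so a width of exactly 0.5 is kept. The
correction runs before extraction selection, so zeroed samples fall below
the purity threshold (default 0.20, compared with ≥) and are excluded.
Extraction keeps the single highest-purity sample per (patient, tissue
area); ties break to the lexicographically smaller sample id. The tissue
areas are primary (fallopian tube, ovary), proximal metastasis (omentum,
mesentery, peritoneum), ascites, and other. Relapse samples are eligible
for extraction by default; `exclude_relapse=True` restricts them to
assignment only.

## SV event features

Junctions are clustered by single-linkage breakend proximity (default
5 kb, the base proximity convention of SV-resolution tools; in 1-D only
position-adjacent breakends need linking, transitivity supplies the rest).
Cluster classification: singleton DEL/DUP → deletion/duplication (event
length = |posB − posA|); singleton translocation with a rounded-CN step
≥ 1.0 at either breakend → unbalanced translocation (no step measurable →
"CN unavailable", left unlabeled); a pair of opposing-orientation
inversions (or translocations) whose breakends mutually pair within
proximity → reciprocal; a pair excising a donor interval ≤ 100 kb and
re-joining it ≥ 1 Mb away or on another chromosome → insertion; any
junction flagged LINE → LINE, which suppresses the deletion/duplication
label of that cluster and does not count toward insertions. Two-junction
clusters matching neither topology count in the intra/inter and
compact/sparse partitions but in neither simple nor complex tallies. A
cluster is compact iff its breakend footprint span on **every** touched
chromosome is ≤ 5 Mb (a declared bound; the notion of a "restricted area"
has no published number).

The chromothripsis-like detector flags a chromosome iff one cluster
contributes ≥ 6 intrachromosomal junctions on it and a run of ≥ 10
consecutive segments alternates between exactly two rounded CN states while
overlapping that cluster's footprint. This echoes the spirit of
high-confidence chromothripsis callers (alternating CN states plus a dense
cluster) but is deliberately simplified — it is not equivalent to graph- or
read-level callers and is documented as an approximation.

Breakpoint density bins every breakend into fixed 0.5 Mb windows anchored
at position 0; the bin total is exactly twice the junction count.

## Copy-number features

Deletion/duplication magnitude are the length-weighted 20th/80th
percentiles (inverted-CDF rule) of log(cn/ploidy); length weighting keeps
tiny segments from dominating, and cn = 0 is clipped to 0.01 before the
log. Changepoints are |CN difference| across adjacent same-chromosome
boundaries. Oscillation chains are maximal runs (≥ 3) of consecutive
segments alternating between exactly two round-half-up CN states; adjacent
maximal runs may share one boundary segment. Segments-per-arm counts a
segment in every arm it overlaps. Segments-per-5Mb counts a segment in
every fixed window it overlaps, with windows below 2 overlapping segments
omitted: with a full-coverage segmentation every window contains at least
one segment, so single-segment windows measure genome size, not
fragmentation, and would contribute a near-constant ~550-count column that
swamps the count matrix (`min_count` is configurable; 1 restores the pure
overlap rule).

## Discretization and the 44-column layout

Continuous families are discretized by models fitted once on the
extraction samples and frozen; assignment never refits. Jenks natural
breaks are computed by the exact Fisher dynamic program (O(k·n²),
vectorized) minimizing within-class squared deviation; breaks are the
upper edge of each lower class, and binning is value ≤ break with
open-ended extremes. Length-valued families are log10-transformed before
fitting. Segments-per-5Mb uses a 1-D Gaussian mixture (EM, k-means++-style
init, fixed seed, BIC selection over 1..3 components; variance floored at
1e-6 × data variance) with breaks at posterior crossovers between
mean-adjacent components; a single-component winner or a break-count
mismatch falls back to quantile tertiles and is flagged degenerate. A
family whose pooled values have too few distinct levels gets one class per
level (flagged degenerate) with all histogram mass in the low bins, so the
column count never changes.

The layout (version `v1`, configurable) totals 44 columns: 21 SV — simple,
complex, intra, inter, compact, sparse (1 each), deletion and duplication
length (5 Jenks bins each on log-length), insertion, reciprocal,
unbalanced translocation, LINE, chromothripsis (1 each) — plus 23 CN —
deletion and duplication magnitude (3 Jenks bins each), segment size (3,
Jenks on log-length), segments per 5 Mb (3, GMM), oscillation chain length
(3), segments per arm (3), changepoint (5). Scalar families contribute one
count in their bin; list families are histogrammed.

## Signature model

KL-NMF uses multiplicative updates with convergence when the relative
divergence change is below 1e-8 (checked every 10 iterations) or 10,000
iterations; non-increase of the divergence is asserted every 100
iterations. All-zero rows/columns are dropped and re-inserted as zeros.
Signature columns are L1-normalized with the scale absorbed into the
activities, and results are bit-reproducible given the seed.

Rank selection: for each candidate rank k, each bootstrap Poisson-resamples
every count entry and is factorized from several random starts; the pooled
signature columns are clustered into k groups by cosine-distance k-medoids
(k-means++-style seeding, alternating medoid updates). The per-rank mean
silhouette is reported as stability, but the selection gate is the
**minimum per-signature** (per-cluster) silhouette — the criterion
extraction tools apply per signature. On planted-rank cohorts the mean
silhouette at rank K+1 frequently stays above 0.8 because the split
cluster is still tight, whereas the minimum collapses to ≈ 0, so gating on
the minimum recovers the true rank; the selected rank is the largest one
with minimum per-signature silhouette ≥ 0.8 (fallback: the rank maximizing
it, flagged). Consensus signatures are the cluster medoids, ordered by
total weight against the pooled matrix and named SCN-A, SCN-B, …

Assignment solves per-sample NNLS on the signature matrix, then prunes
backwards: repeatedly drop the signature whose removal increases the
relative L2 reconstruction error least, while that increase stays below
0.01, refitting after each drop. An all-zero sample row yields all-zero
activities.

## Subtyping and statistics

Consensus clustering: `n_resamples` subsamples of 80% of samples,
average-linkage hierarchical clustering under 1 − Pearson distance on
exposure fractions (constant rows get distance 1), consensus(i, j) =
co-cluster count / co-sample count (never-co-sampled pairs get consensus 0
with a warning), final labels from average linkage on 1 − consensus. The
cluster number, unless fixed, is the consensus-CDF elbow: the largest k
whose relative area increase is ≥ 0.1. The raw "maximum delta area" rule
degenerates to the smallest tested k (whose delta equals its whole CDF
area) and mis-recovered planted partitions, so the elbow rule is used. The
optional two-pass mode for separating a quiet-genome cluster first is not
implemented; single-pass clustering recovered planted structure in all
tests.

Patient stability counts a patient stable iff all its labeled samples share
one cluster; single-sample patients are stable by definition. The
validation classifier is a random forest on exposure fractions (500 trees,
OOB accuracy reported, ≥ 5 samples per class required).

Kaplan–Meier, the multi-group log-rank test (observed minus expected with
hypergeometric covariance; chi-square on the first g−1 components via
pseudo-inverse), and Harrell's C (comparable pairs where the earlier time
is an event; risk ties count ½; tied times skipped) are implemented
directly and cross-checked against lifelines in the tests. Cox
proportional hazards is delegated to lifelines. Mann–Whitney uses the
exact null when both groups are ≤ 8 without ties, otherwise the
tie-corrected normal approximation (scipy); BH correction is applied per
declared test family, never globally. The median split assigns patients
strictly above the cohort median of per-patient sample-median activity to
"high", the rest to "low".

## Synthetic cohorts

The generator emulates segment/junction profiles as mixtures of six
process templates. Event counts are Poisson with rate = template rate ×
mixture weight; lengths are log-normal per template. Profiles are built
from copy-number-altering intervals over an integer baseline
(round-half-up of the mixture ploidy): deletions and fragmentation losses
are placed mutually disjointly and never deeper than the baseline, so the
profile never clamps below zero and every DEL/DUP junction retains a CN
step at both breakends — the junction–segment concordance the validator
checks. Reciprocal and insertion events are balanced (junctions without CN
change); unbalanced translocations attach a 1–6 Mb terminal-style loss at
one breakend; complex events chain 8–12 junctions through knots with
alternating elevated intervals, producing both a single dense cluster and
a ≥ 10-segment oscillating run (exercising the chromothripsis detector);
focal amplifications add +6 or more copies over 0.5–3 Mb.

Template calibration is qualitative, not fitted to any cohort: BRCA1-like
deletions are log-normal with median 100 bp (≥ 60% of mass below 200 bp)
and duplications mostly 1–45 kb; BRCA2-like deletions sit essentially
below 36 kb with elevated unbalanced translocations; the tandem-duplicator
stacks multi-copy duplications at shared loci (pyrgo-like, so stacks
cluster as complex events) and adds long oscillation chains; the amplifier
concentrates focal amplification and inter-chromosomal events on few
chromosomes; the WGD template is tetraploid with heavy genome-wide
fragmentation; the simple genome averages ≤ 2 junctions. Each template
also has a characteristic copy-number step size (1, 2, or 3 copies, plus
high-level amplification steps) and a chromosomal concentration (regional
instability on 4–14 chromosomes vs genome-wide): both are biologically
motivated — deep deletions, stacked tandem duplications, localized
shattering — and were calibrated once so the six mean 44-feature profiles
satisfy the generator's declared separability contract (pairwise cosine
≤ 0.8), which the count features would otherwise violate because every
junction feeds the same changepoint/segment-count families.

Purity is Uniform(0.15, 0.95) with a 5% chance of an unreliable (width
0.6) purity range; patients share a Dirichlet base mixture that each
sample jitters (concentration 80), giving realistic multi-sample
stability. Survival is exponential with a proportional-hazards link on the
patient's dominant template (log-hazards: BRCA2-like −1.1 < BRCA1-like
−0.9 < simple −0.4 < tandem-dup 0.3 < WGD 0.4 < amplifier 0.5; declared
constants chosen so survival tests have signal, not estimates of anything),
with uniform censoring.

What the generator does **not** emulate: purity/ploidy distortion of
observed copy numbers (CN is the true tumor profile), subclonal fractions,
caller noise or blacklist artifacts, realistic breakpoint sequence context,
and real HGSC cohort frequencies. Passing tests therefore demonstrate that
the pipeline recovers planted structure under idealized calling, not that
it reproduces any real cohort's biology.

## Problem sizes and determinism

Simulation-based tests run at reduced but non-trivial scale chosen as the
package's own defaults for desk-scale verification: rank recovery uses 60
samples × 10 replicates per planted rank with 10 Poisson bootstraps over
ranks 2–7; consensus recovery uses 80 samples × 300 resamples; calibration
uses 10,000 null replicates; the end-to-end determinism check runs a
24-patient cohort twice and compares output bytes. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; seeds for
nested loops are derived as seed lists, keeping every stream independent
and reproducible. Reports and tables avoid timestamps so reruns are
byte-identical.

## Known limitations

* The 44-column layout reconstructs a plausible per-family bin split; the
  field's published split is not public in the main text of any source, so
  the layout is versioned and swappable.
* The chromothripsis detector is a declared simplification (see above).
* Jenks DP is exact but O(k·n²); pooled families beyond ~10⁵ values would
  warrant the O(k·n log n) SMAWK variant.
* Automatic consensus-k selection by the CDF elbow over-splits genuinely
  2-cluster data in favor of small substructure; fix `k` when it is known.
* Harrell's C is O(n²); adequate for cohort-scale patient counts.
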