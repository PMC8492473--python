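# Methods

`tereawaken` implements a TE-centric regulatory-genomics pipeline:
quantification of transposable-element (TE) expression at family and copy
resolution, negative-binomial differential testing, construction of
gained/lost chromatin-accessibility peak sets, TE-family enrichment in
accessible chromatin against a shuffled-placement null, a permutation test
for proximity between upregulated TE copies and deregulated genes, and Tn5
footprint-occupancy scoring. A synthetic-data generator provides ground
truth for every stage, so the statistical behaviour of the whole pipeline
is verifiable without sequencing data.

## Coordinate conventions

All intervals are 0-based half-open (`[start, end)`), the native BED
convention. A gene's TSS is its 5' end under this convention: `start` on
the + strand, `end - 1` on the −. Overlap means ≥ 1 shared bp everywhere;
bookended intervals (gap 0) are *merged* during consensus construction
(mergeBed's default) but do *not* overlap for gained/lost labelling.

## TE quantification

Copy-level counts use uniquely aligned reads only — a multi-mapping read
carries no positional evidence at copy resolution (the upstream
equivalent is extracting unique alignments with a MAPQ filter). A unique
read increments the copy it overlaps by ≥ 1 bp; when it overlaps several
copies it is assigned to the copy with the largest overlap, ties broken
by lexicographically smallest `copy_id`. Strict intersection semantics
would discard such reads as ambiguous; the largest-overlap rule keeps
them while staying deterministic and testable. Counting is unstranded.

Family-level counts keep multi-mappers. Each read distributes one unit of
weight over the families containing its candidate loci, either uniformly
or by EM: initialize from the uniform split, then repeatedly reassign each
ambiguous read proportionally to current family abundances (unique counts
plus ambiguous weight), stopping after `em_iters` (default 100) rounds or
when the largest family-weight change drops below 1e-8. This is the
standard multi-mapper mixture model used by family-level TE quantifiers;
we do not reproduce any specific tool bit-for-bit — the pipeline only
needs defensible family abundance estimates, and the EM's assignment
log-likelihood is verified non-decreasing in tests. Candidate loci
falling outside every TE copy feed an explicit "non-TE" sink so that read
mass is conserved exactly (asserted in tests); the sink is reported in
the count matrix metadata.

One deliberate divergence from common practice: multi-mappers retain *all*
candidate loci rather than one randomly chosen placement, which makes the
ambiguity structure explicit instead of hiding it in an aligner's RNG.

## Differential testing

Counts are normalized with median-of-ratios size factors (geometric-mean
reference; features containing a zero are excluded from the reference,
with a total-count fallback if none survive). TE families are normalized
*together with genes* in the joint matrix — family counts are a small
fraction of the library, so normalizing them alone would absorb the very
signal being tested.

Each feature is tested with a Wald test on the log fold change under
NB(mean μ, Var = μ + αμ²). Group means are maximum-likelihood fits with
size-factor offsets (IRLS on the log link; with equal factors this is the
plain normalized mean). Dispersion α is estimated by method of moments
from pooled within-group variances, floored at 1e-8, and then each
per-feature estimate is floored by a mean-binned trend across features
(the larger of the two is used). The trend floor is the small-sample
device: raw MoM estimates at 3 vs 3 are noisy enough to break the normal
approximation, and sharing information across features in this way keeps
the normal-reference Wald test calibrated (measured type-I rate 0.052 at
a nominal 0.05 under null simulations) without the power loss a
heavy-tailed reference distribution would impose. A group with zero total
counts gets a half-count floor so fold changes stay finite. p values are
BH-adjusted within the submitted feature batch; all-zero features are
reported `untested` and excluded from the BH denominator.

Calls use a **linear 1.5-fold cutoff with p_adj < 0.05** (`up` requires
log2 fc ≥ log2 1.5 ≈ 0.585, `down` symmetric). The boundary is strict in
the sense that log2 fc = 0.58 does not qualify.

FLASH-style bait-versus-control binding uses a per-element Welch
unequal-variance t-test on normalized counts with **unadjusted p < 0.05
and strictly fold change > 1.5** — deliberately looser than the
expression analysis, matching how pull-down enrichment lists are built.
Whether normalization precedes the Welch test is an analysis convention;
we normalize by default and expose the choice (`normalize=`).

The `--allow-no-replicates` escape hatch substitutes a single pooled
dispersion and marks results low-confidence via a warning; it exists for
exploratory use only.

## Peak operations

Gained peaks for a time point versus baseline follow the two-step
bedtools-style construction: (1) concatenate and merge the two peak lists
into disjoint consensus regions; (2) label each consensus region gained /
lost / common by which inputs it overlaps. The three labels provably
partition the consensus (property-tested on random fixtures), and a
consensus that fails to cover an input peak is rejected rather than
silently mislabelled. Peaks shorter than 300 bp are discarded before TE
analysis; "smaller than 300 bp" is read as *keep length ≥ 300*, i.e. the
boundary is inclusive. Count-based peak significance delegates to the
same NB machinery as expression (one NB engine serves both the
edgeR-style and DESeq-style usages; a deliberate simplification).

## TE-family accessibility enrichment

Copies are padded ±1 kb (clipped at chromosome ends) and the observed
statistic is the number of (peak, copy) overlap *events* per family — a
peak overlapping k padded copies contributes k. Event counting (rather
than distinct-peak counting) was chosen because its expectation under
uniform placement has a closed form, which the null is verified against.

The null relocates every padded copy uniformly within its own
chromosome's allowed space (chromosome minus excluded regions), length
preserved, 1,000 times by default; shuffled copies may overlap each
other. Shuffling the TEs (not the peaks) follows the shuffle-based
enrichment tools this emulates; the same-chromosome constraint is an
interpretation — disabling feature linkage does not imply relocating
across chromosomes.

Significance per family: exact binomial tail with n = number of peaks and
p = null_mean / n (upper tail for enrichment, lower for depletion), plus a
hypergeometric tail on base pairs (urn = genome bp, successes = padded
family bp, draws = total peak bp, observed = overlap bp) — stated
explicitly because bp-level 2×2 constructions vary between tools.
Families are finally crossed with the differential-expression calls: the
reported hits are families simultaneously deregulated and
enriched/depleted in the tested peak set.

## TE-copy / gene proximity

Each upregulated copy is assigned to the gene whose TSS is nearest
(closest-feature semantics: ties on distance go to the first gene in
(chrom, start, gene_id) order; the distance sign is relative to the
copy's orientation, positive downstream). Genes assigned at ≤ 30 kb
(inclusive at exactly 30,000 bp) form the proximal list — note this is
the *closest-gene-then-window* list the bedtools `closest` workflow
produces, so at most one gene per copy.

The observed overlap between the proximal list and the deregulated genes
is tested three ways: hypergeometric upper tail, two-sided Fisher, and an
empirical background — draw |DEG| genes without replacement from the
*remaining* genes (universe minus DEGs; a flag switches to the full
universe) 10,000 times, record each overlap with the proximal list, and
use the mean as the expected count of an exact binomial upper-tail test.
"Remaining genes" is our reading of an ambiguous background description;
both readings are implemented. The resampling uses random-key selection
(argpartition of uniform keys), exact without-replacement sampling in
vectorized form.

Calibration: with genes placed independently of TEs and DEGs drawn at
random, the binomial-vs-null test rejects at α = 0.05 in 3.6–4.4% of 500
simulated datasets (slightly conservative, as expected: the binomial
reference has more variance than the true hypergeometric overlap
distribution, and the counts are discrete).

## Footprinting

ATAC fragment 5' ends are shifted +4 bp (+ strand) / −5 bp (− strand) to
centre Tn5 insertion events; out-of-chromosome events are dropped and
counted. Profiles are per-site, per-strand insertion counts over
[−flank, motif, +flank], averaged across sites (optionally normalized to
a per-bp rate summing to 1 per strand).

The footprint occupancy score per site is

    FOS = (C + 1) / max(L, 1) + (C + 1) / max(R, 1)

with C the insertion count in the motif span and L, R the counts in
`flank_width` bp (default 35) immediately left/right. Pseudocounts keep
the score defined on sparse data; lower FOS = deeper protection. The
upstream literature names a script rather than a formula, so the
flank-ratio form above is declared, versioned, and configurable
(including whether flanks are fixed-width; motif-length-scaled flanks are
obtainable by passing a different `flank_width`). FOS is verified to
decrease monotonically in simulated footprint depth (Spearman ρ = −1.0
across an 11-point depth grid). Footprint *detection* is out of scope:
sites are an input.

Condition comparisons are paired two-tailed t-tests on log2(FOS), pairing
sites by id; identical inputs return p = 1 exactly.

## Synthetic-data generator

What it emulates, per stage:

- **Genome**: equal-length chromosomes with non-overlapping excluded
  regions (gap/blacklist stand-ins) covering a target fraction, default
  5% in the end-to-end study. Excluded regions are barred from all random
  placement, mirroring how blacklists restrict shuffling.
- **TE annotation**: copies placed uniformly in allowed space with
  RepeatMasker-style `name:superfamily:class` labels; copies may overlap
  each other (nested repeats do) but never excluded regions.
- **Counts**: NB(mean = size factor × base mean × fold change, Var =
  μ + αμ²) per feature and sample, two conditions; dispersion 0 degrades
  to Poisson. The study's default dispersion (0.05 for the planted-effect
  studies, 0.1 for null calibration) is a conventional bulk-RNA-seq
  value — the real data's noise model is unknowable from a desk, so these
  are generator conventions, not estimates.
- **Reads**: per-copy Poisson read counts placed uniformly inside copies;
  a tunable fraction are multi-mappers reporting 1–3 extra placements in
  sibling copies of the same family (repeats are homologous within
  families, so ambiguity is family-structured — the property family-level
  EM relies on).
- **Peaks**: uniform placement over allowed space except that each peak
  hits the ±pad neighbourhood of a chosen family with probability
  min(factor × q, 1), where q is the uniform-placement hit probability;
  factor 1 reproduces uniform placement *exactly* (chi-square-verified),
  which is what makes the type-I experiments honest.
- **Gene placement**: a chosen fraction of TSS within the window of
  designated copies (pairs recorded as truth), the rest rejection-sampled
  strictly beyond the window; `frac_proximal=None` places genes uniformly,
  the TE-independent configuration used for null calibration.
- **Insertion profiles**: per-position Poisson at the background rate,
  reduced by the footprint depth inside the motif span.

What it does **not** emulate: sequence content (no FASTQ, no alignment
error), fragment-length structure, GC or mappability biases, correlated
replicates, overdispersed peak placement, or single-cell sparsity.
Passing tests therefore demonstrate correctness of the *statistical
procedures* under their stated models, not robustness to the artefacts of
real libraries.

## Default study scale

The end-to-end study uses 2 chromosomes × 1 Mb, 5 families × 20 copies
(300–600 bp), 1,000 genes (10% proximal to the planted family's copies),
3 vs 3 replicates, 120/160 peaks of 400 bp, 300 footprint sites, with a
4-fold planted expression effect and a 5-fold peak-placement excess.
These sizes were chosen so every stage has unambiguous power (the planted
family is recovered and flagged in 100/100 seeded runs) while a complete
run takes under a second; calibration studies (500-dataset proximity
null, 10 × 5,000-feature NB null) run in well under a minute. Validation
studies use 1,000 shuffles and 1,000–10,000 resamples as in the
production defaults.

## Numerical choices and degenerate inputs

- Binomial/hypergeometric tails are exact (`scipy.stats` sf/cdf), verified
  against rational-arithmetic enumeration to < 1e-10.
- Degenerate nulls: observed = 0 → p = 1; null mean 0 with observed > 0 →
  p = 0 with a warning; zero-variance Welch with equal means → p = 1.
- The NB group-mean IRLS stops at 20 iterations or relative change
  < 1e-10; with equal size factors it is exact in one step.
- Bounded-retry placement (1,000 attempts) fails loudly naming the
  chromosome rather than silently under-filling.
- All generators are deterministic given a seed; the end-to-end pipeline
  derives per-stage seeds from one master seed via a seeded generator.

## Known limitations

- The Wald NB test is a stand-in for the DESeq/edgeR fits the original
  analyses used; agreement is at the level of calibration and parameter
  recovery, not bit-parity.
- The proximity "proximal list" inherits the closest-gene restriction (at
  most one gene per copy); genes within the window of a copy but closer
  to another gene are not listed.
- The shuffle null relocates copies independently, ignoring the spatial
  clustering real TE families show; the enrichment p-values are exact
  only under that independence.
- Family labels are treated as flat identifiers; no aggregation to
  superfamily/class level is provided.
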