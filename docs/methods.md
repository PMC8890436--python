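# Methods

## Donor model

A donor site is represented by a 9-mer: the last 3 exonic and the first 6
intronic nucleotides, with the invariant GT at intronic positions 1–2 fixed
during candidate generation but included in the scored window.  The scorer
is a maximum-entropy model: among all distributions over the enumerated
4^9 k-mer space whose marginals over a chosen family of position subsets
match the training donors, it selects the one of maximal Shannon entropy,
and scores a sequence as the log2 ratio of its model probability to a
background probability (uniform by default).  Scores are therefore signed;
zero means "no more donor-like than background", and a sequence assigned
zero model probability scores −∞ and fails every finite threshold.

The default constraint family is all single positions plus all adjacent
pairs.  This captures first-order composition and nearest-neighbour
dependence, keeps the number of constrained cells small relative to any
realistic training set, and — because the constraint graph is a chain —
makes the fit exactly decomposable.  Constraint sets are configurable; a
plain PWM (`fit_pwm`) is the special case of singleton constraints only,
and the test suite asserts the two coincide there.

**Fitting.** The fit is cyclic iterative proportional scaling: starting
from the uniform table, each constrained marginal is matched exactly in
turn, sweeping until the largest marginal discrepancy falls below `tol`
(default 1e-6; default cap 10,000 sweeps, with a diagnostic warning on
non-convergence).  This has the same fixed point as damped parallel
scaling — the I-projection of the uniform distribution onto the constraint
set, i.e. the maximum-entropy solution — and converges in a single sweep
for decomposable constraint families such as the default chain.  The test
suite checks agreement (KL < 1e-6) with an independent oracle that
maximizes entropy directly over the probability simplex by trust-region
constrained optimization, including a non-decomposable (triangle)
constraint family.

**Smoothing.** Target marginals are taken from the training distribution
mixed with a uniform pseudo-mass of `4 × pseudocount` observations
(default pseudocount 0.5, so each singleton marginal cell receives +0.5
pseudo-counts).  Smoothing the joint distribution once and deriving every
constrained marginal from it keeps the constraint system self-consistent;
smoothing each marginal table separately would make singleton and pairwise
targets mutually contradictory (their implied totals differ), and no
distribution — hence no fit — could satisfy them.

**Thresholds.** The catalog's default score threshold is 0 and inclusive
(score ≥ 0 passes); whether equality passes is configurable because usage
in the source material is ambiguous between "threshold of 0" and "higher
than 0".  A stringent preset of 6.77 (the level that retains ~80% of
annotated donors in the human genome) can be passed explicitly.  Exact
numeric equality with any previously published donor-score tables is a
non-goal; the model family and score semantics are what is reproduced.

## Candidate catalog

Introns are the gaps between consecutive CDS-bearing exons of multi-exon
coding transcripts (GTF input, 1-based inclusive; all internal coordinates
0-based half-open; BED-like output 0-based half-open).  On the transcript
sense strand, every GT at intron offset 1 ≤ d ≤ 1000 with at least 20 nt of
intron remaining is a candidate that would extend the upstream exon by d
nucleotides.  GTs coinciding with annotated donors — the union over all
supplied annotation files, including transcripts excluded from scanning —
are dropped.  Candidates sharing (chromosome, strand, GT position, parent
donor) across transcripts are one record listing all transcript ids.

Classification continues the upstream exon's reading frame through the
extension.  The frame offset at the donor is the cumulative CDS length up
to that exon end mod 3, taken from the longest-CDS transcript when
transcripts disagree (disagreements are logged).  A STOP codon qualifies
when at least one of its bases lies in the extension and the codon ends at
or before the candidate GT; a codon that would run past the GT is never
completed in the extended exon and does not count.  Sites with an in-frame
STOP are `LSS`; STOP-free sites are `adSS_3n` or `adSS_fs` by extension
length mod 3.  Candidates with ambiguous bases (N) in the scored window or
extension are rejected with a recorded reason.

## Quantification and activation calling

Junctions are keyed by their exact genomic gap (0-based half-open), with no
fuzzy merging, since latent-donor detection needs exact donor coordinates;
strand comes from the annotation at the donor.  Latent usage is
`reads_latent / reads_canonical` for the same intron; it is self-normalizing
across sequencing depths and is left undefined (and the site excluded, with
a reason) when canonical support is zero — no pseudocounts.  Depth
normalization to reads-per-million exists only for cross-sample tallies of
supported sites.

A site passes the initial activation criteria when, with usage defined in
all four samples, one replicate (either may play the primary role) has
≥ 4 latent reads and ≥ 1.5-fold usage increase and the other has ≥ 1 latent
read and any increase (fold strictly > 1).  Control usage of zero with
nonzero case usage counts as infinite fold.  The stringent criteria impose
4 reads / 1.5-fold on both replicates, so stringent calls are a subset of
initial calls by construction.

The coverage screen quantifies "reads present throughout the extension" as
100% of positions with depth ≥ 1 in both case replicates, and "consistently
higher in cases" as ≥ 95% of positions with higher normalized depth than
the replicate-paired control (normalization factor: the sample's canonical
split-read support for that donor).  Both fractions are configurable; the
defaults are deliberately strict and monotone.  Additional false-positive
filters referenced but not specified in the source material are not
implemented; the two fractions are the extension points.

Calls are ranked by per-replicate one-sided Fisher's exact tests on
`[[latent_case, canonical_case], [latent_control, canonical_control]]`,
combined by Fisher's method (−2Σln p against chi-square with 2k degrees of
freedom; k = 2 replicates → df 4), with the fold reported as the geometric
mean over replicates.  Ranking p-values are not multiplicity-corrected (the
output is a ranking, not a thresholded discovery set).  Label switching
reruns the identical pipeline with case/control labels exchanged and flags
its output; the class-bias test then compares activation counts of two site
classes under true vs switched labels with a one-sided Fisher test, first
row enriched in the first column (callers order rows explicitly).

Composite profiles average the per-base normalized case/control fold over
replicates (sense-oriented, measured from the annotated donor), floor raw
depths at one read-equivalent so folds stay finite where the control lacks
coverage, and take the pointwise median across sites; shorter sites simply
drop out of positions beyond their length.  The 95% band uses
distribution-free order-statistic (binomial) bounds for the median, which
are degenerate below 3 sites and flagged as such (a bootstrap alternative
was considered and rejected as no less arbitrary and considerably noisier
at these n).  The standardized representation averages the fold within 100
equal-width bins along each extension.

Gene-set enrichment is an inclusive upper-tail hypergeometric test against
user-supplied GMT collections after intersecting sets and query with an
explicit, caller-provided universe (no universe is assumed because the
appropriate one — all genes with catalog assignments vs all annotated
genes — is a study-level decision).  Bonferroni correction is applied both
within each collection and globally over all supplied sets.

## Synthetic data

The generator emulates the statistical structure the caller assumes, not
any particular genome.  Genes alternate strands along one chromosome; every
exon is fully coding with length divisible by 3, so the frame offset at
each donor is 0; annotated donors and planted candidate donors are drawn
from a fixed consensus-shaped positional frequency table (CAG|GTAAGT-like),
with candidate 9-mers rejection-sampled (cap 10,000 attempts) until their
model score lands in the requested window — decoupling score control from
model internals.  Extensions are built from non-STOP codons with a STOP
planted for LSS sites; at most one site is planted per intron.

Counts: canonical junction reads per intron and sample are negative
binomial in the mean–dispersion parameterization (gamma–Poisson mixture),
the standard overdispersion model for bulk RNA-seq; latent reads are
Poisson around canonical × usage, where usage is the baseline fraction
(default 0.01) times per-replicate lognormal jitter (σ = 0.1), multiplied
by the effect fold (default 5) in case samples for the activated subset.
Extension coverage is per-nucleotide Poisson around the latent support —
nucleotide-resolution noise is what makes the 95%-of-positions profile
criterion meaningful; coarser block noise would silently turn it into an
all-blocks test.  Defaults: 8 genes of 3–4 exons, introns 150–300 nt,
planted 6 LSS / 4 adSS_3n / 4 adSS_fs with half activated, canonical mean
500 (at the >200M-read depths this experiment design assumes, expressed
canonical junctions carry hundreds of split reads; this also places the
mean case latent support at 25, squarely in the ≥10-read regime the
recovery property describes), dispersion 0.1.  Everything is deterministic
given (params, seed), and SAM emission reproduces the junction tables
exactly on re-extraction.

What the generator does **not** emulate: alignment artifacts and multi-
mapping, positional coverage biases (GC, 3' bias), unannotated exons,
overlapping genes, NMD-driven depletion of PTC-bearing isoforms, and
isoform deconvolution when one donor joins several acceptors.  Passing the
planted-truth tests therefore demonstrates that the pipeline's logic is
correct and its criteria calibrated under its own model assumptions — not
that those assumptions hold for any particular real dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data at
desk scale: toy genomes of ~15–25 kb with ~20 introns, 20 seeds for
catalog/brute-force agreement and planted-truth recovery, 50 simulated
experiments for null label parity, donor models at k ≤ 4 for the
simplex-oracle comparison, and exhaustive 2×2 tables with totals ≤ 40 for
the exact-test comparison.  Genome-scale catalogs (10^6 sites) are out of
scope for the bundled data but not for the code, which is linear in intron
length.

Numerical details: iterative scaling tolerance 1e-6 on the max marginal
discrepancy; p-values of exactly 0 are clamped to the smallest positive
float before Fisher's method, with a warning; zero-margin contingency
tables give p = 1; ties in Spearman's correlation use midranks and constant
vectors raise rather than return NaN; junction tables and model tables
round-trip exactly through their plain-text formats (floats serialized via
`repr`).
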