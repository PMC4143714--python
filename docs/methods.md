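# Methods

## The problem

Family-based genetic studies record pedigrees; genotype data frequently
contradict them.  Undocumented nonpaternity, adoptions, sample
duplications and swaps, and cryptic relatedness among "unrelated"
panels all distort both linkage and association analyses if undetected.
Genome-wide SNP data carry enough information to estimate the true
genetic relationship of every pair of genotyped individuals and to test
it against the recorded one.  `kinscan` implements that workflow:
likelihood-based estimation of pairwise IBD sharing, classification of
pedigree-implied relationships, outlier flagging, and a formal
likelihood-ratio test with simulated significance.

## Model

The relatedness of a non-inbred pair is summarized by the IBD
distribution p = (p0, p1, p2): the probability that a random autosomal
marker carries 0, 1 or 2 alleles identical by descent between the two
individuals.  With biallelic genotypes G_m (minor-allele dosage) at
marker m and minor frequency q_m, the log-likelihood over M markers is
the mixture

    L(p) = sum_m log sum_{i=0,1,2} P(G_m | D_m = i) p_i ,

where the conditional probabilities P(G_m | D_m = i) follow from HWE by
allele-level enumeration (for example P(2,2|2) = q^2, P(2,2|1) = q^3,
P(2,2|0) = q^4).  The model assumes:

* markers unlinked and in linkage equilibrium (the input should be
  LD-pruned; the estimator treats markers as independent),
* Hardy-Weinberg proportions at the supplied allele frequencies,
* non-inbred pairs (the 3-state model; pairs involving an inbred
  individual are refused rather than approximated, and whole-sample
  scans code them as "other"),
* autosomal diploid inheritance (sex chromosomes are out of scope).

L(p) is concave in p (a sum of logs of affine functions), so the MLE is
unique and any ascent method finds it.  `em_mle` uses plain EM from the
interior point (1/3, 1/3, 1/3) with tolerance 1e-6 on the
log-likelihood change and at most 1000 iterations.  The estimate is
*unconstrained* on the simplex — no "possible triangle" restriction —
which is what lets a sample duplicate reach the MZ-twin vertex
(0, 0, 1) rather than stopping at the full-sib point.

The whole-sample scan path (`ibd.estimate_pairs`) computes the same MLE
with a SQUAREM-style accelerated EM in float32, warm-started at the
truncated moment estimate.  Concavity guarantees the same maximizer;
the acceleration is safeguarded (a cycle falls back to its plain double
EM step whenever extrapolation does not improve the log-likelihood) and
stops on the same tolerance.  Plain EM needs on the order of a thousand
iterations for boundary solutions (unrelated pairs); the accelerated
path typically needs twenty to thirty cycles.

The method-of-moments comparator (`mom_estimate`, the approach PLINK
takes) equates observed IBS-0 and IBS-1 counts to their
frequency-dependent expectations and solves sequentially; the raw
solution may leave [0, 1] and is reported alongside the PLINK-style
truncated-and-renormalized version.  It is several-fold noisier than
the MLE on the same input, which is the practical argument for the
likelihood approach.

## Relationship catalog and classification

Pairwise kinship phi is computed by the classical recursion (founders
unrelated and non-inbred; phi(a,a) = (1+f_a)/2; descend through the
deeper member's parents).  For non-inbred pairs the prior IBD
distribution follows from parental kinships:

    p2 = phi(Fa,Fb) phi(Ma,Mb) + phi(Fa,Mb) phi(Ma,Fb)
    p1 = 4 phi(a,b) - 2 p2 ,      p0 = 1 - p1 - p2 .

Founders are given hidden dummy parents internally so the formula is
total (this reproduces parent-offspring as (0, 1, 0) without a special
case).  Each pair is matched to the catalog of eleven relationship
types at tolerance 1e-9.  Three types share (0.5, 0.5, 0) — half-sib,
grandparent-grandchild, avuncular — and are separated structurally
(shared parent / grandparent path / full sib of a parent); likewise
(0.75, 0.25, 0) resolves to half-avuncular when one member is a
half-sib of the other's parent and to the first-cousin class otherwise
(so e.g. a great-grandparent pair, IBD-equivalent to first cousins, is
labelled with the first-cousin code — classification is by IBD class,
which is all the likelihood can see).  Pairs matching no row (e.g.
double first cousins) are coded 99 and excluded from outlier flagging.
MZ twins cannot be inferred from structure; the MZ row exists as an
alternative hypothesis and for truth annotation.

## The MLRT

For a pair with putative relationship R0 and alternatives A (all other
catalog rows by default):

    MLRT = max_{R1 in A} log L(R1) - log L(R0) ,

with every likelihood evaluated at the relationship's prior IBD vector.
Because A is a discrete set rather than a nested parametric family,
2·MLRT has no chi-squared reference distribution; significance comes
from simulation.  Genotype pairs truly related as R0 are generated on
the pair's own marker panel — by i.i.d. per-marker IBD draws (unlinked
mode, the default) or by gene-dropping through the canonical minimal
pedigree with Haldane-model recombination along the cM map (linked
mode, no crossover interference, sex-averaged distances) — and

    p = (1 + #{simulated MLRT >= observed}) / (reps + 1) ,

the add-one estimator, which can never return exactly 0 (reported
zeros in this kind of analysis mean "below resolution").  The best
alternative is then re-tested as its own null to give the "plausible
relationship" p-value; when the plausible type is MZ and the genotypes
are literally identical there is nothing to simulate and the p-value is
reported as not available.  Ties among alternatives resolve to the
smallest code, and the three IBD-equivalent types are reported as the
equivalence class HS/GPC/AV (their likelihoods are identical, a
fundamental non-identifiability, asserted exactly in the tests).

Default reps = 1000.  Testing runs on a random ~2000-marker subsample
by default (estimation uses the full panel); with unlinked nulls the
statistic's null distribution depends only on the subsample's
frequencies.

## Synthetic studies and planted errors

`make_synthetic_study` emulates a multigeneration family study plus an
unrelated panel: configurable numbers of families (default 20, echoing
the scale of large family studies), offspring generations and children
per couple, singletons (default 141) and markers (default 50,000,
minor-allele frequencies Uniform(0.05, 0.5) — the regime left by a 5%
MAF filter), on a uniform 22-autosome, ~3500 cM map.  Each family also
contains one remarriage (a mother with children by two recorded
fathers) so that half-sib structures exist for error-planting.

Three planted-error event types distort the *true* pedigree relative to
the recorded one: sample duplicates (identical genotypes, new id
recorded as a sibling), parent swaps (transmission rewired to a
different true father — an existing member or a hidden outsider —
while the record keeps the original), and cryptic links (two recorded-
unrelated founders generated jointly from the canonical pedigree of a
chosen relationship).  The truth table is computed exactly, by
comparing recorded and true pedigree priors over the closure of touched
individuals and their descendants against every genotyped individual,
so downstream "zero false positives" claims are checked against a
complete list of genuinely distorted pairs, including cascade effects
(a rewired child changes relationships to the whole paternal branch).

Two generator choices matter for interpreting test results:

* **Transmission is per-marker independent by default.**  Real meiosis
  transmits long haplotype blocks, so a real pair's *realized*
  genome-wide IBD fluctuates around the pedigree expectation (for
  grandparent-grandchild or cousin pairs the realized kinship SD is a
  substantial fraction of its mean).  The linked mode (Haldane
  crossovers) reproduces that variance and is used for the MLRT null;
  the default unlinked mode removes it, so that estimator accuracy can
  be assessed against exact expectations.  Passing end-to-end tests
  therefore demonstrate detection of *planted* discrepancies under
  clean sampling noise; on real data, distant relationships scatter
  more widely around their expectations than these tests exhibit.
* **The marker table carries the generating founder frequencies.**
  Estimating frequencies from a small sample feeds correlated noise
  into every pairwise likelihood and inflates apparent relatedness by
  roughly one over twice the effective number of independent
  chromosomes sampled — negligible at a thousand genotyped individuals,
  dominant at desk scale.  Scans of written files recompute sample
  frequencies (whole-sample by default, founders-only via
  `estimate_allele_freqs(..., individual_mask=...)`), matching what a
  practitioner can do with real data.

Other generator non-features: no LD (inputs emulate post-pruning
panels), no genotyping error or mutation, no missingness in generated
data.

## Outlier flagging

A scanned pair is flagged when the Euclidean distance of its estimated
(p0, p1) from the putative relationship's prior (p0, p1) exceeds 0.1.
The threshold is a default, not a decision rule with guaranteed error
rates: at 50k markers the estimator's per-coordinate SD is ~0.01, so
0.1 is far outside sampling noise for catalogued pairs, while clearly
mis-recorded relationships differ by at least 0.17 in this metric.
Pairs coded 99 have no catalog expectation and are never flagged by
this rule.

## Numerical and scale choices

* Catalog matching tolerance 1e-9 (the recursion is exact up to float
  rounding); prior components validated to sum to 1 within 1e-12.
* EM: tol 1e-6 on log-likelihood change, max 1000 iterations, interior
  start; batch path float32 with float64 log-likelihood accumulation.
* Markers with undefined or boundary frequencies, and markers missing
  in either member, are dropped per pair; `commark` counts the markers
  actually used.
* LD pruning removes, within a violating pair, the lower-MAF marker
  (ties: the later in genome order) — a deterministic greedy rule,
  re-checked until every retained window pair satisfies the r^2 bound.
* Genetic-map interpolation clamps to the nearest anchor outside the
  anchor range.
* Ped/map orientation: the minor allele is the less frequent observed
  symbol, ties broken lexicographically, so write/read round-trips are
  byte-stable; the study generator pre-orients its output to the
  realized sample-minor allele for the same reason.
* Scaled-down suite sizes (all chosen to keep each property at several
  standard errors of separation): parameter recovery 50 pairs x 50k
  markers per relationship; MLRT calibration 200 pairs x 2000 markers x
  499 replicates; comparator contrast 500 pairs x 5000 markers;
  end-to-end recovery 10 seeds of a 3-family (2 offspring generations,
  remarriage included) + 12-singleton study at 20,000 markers, where
  the 0.1 flag threshold sits at ~5 SD of estimator noise, as it does
  at the full study scale.

## Known limitations

* Global (genome-average) IBD only: similar relationships (second
  cousin vs unrelated) are not separable; segmental/local IBD methods
  are out of scope.
* Sensitive to mis-specified allele frequencies, hence to population
  structure and admixture; no robust-estimator variant is provided.
* Inbred pairs and X-linked inheritance are refused, not approximated
  (the 9-state condensed-identity machinery is out of scope).
* The MLRT's alternatives are the discrete catalog; an EM-maximized
  unrestricted alternative is available behind a flag but not default.
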