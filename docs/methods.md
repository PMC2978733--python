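# Methods

## Mappability

A position is *mappable* when the k-mer starting there occurs exactly
once in the reference, counting forward occurrences of the k-mer plus
forward occurrences of its reverse complement (equivalently: both
strands). Two consequences of this convention are deliberate:
palindromic k-mers count twice and can never be unique, and k-mers
containing N are assigned frequency 0 (a read never aligns uniquely to
ambiguous sequence). Coordinates are 0-based half-open everywhere; a
k-mer belongs to a locus only if it starts *and* ends inside it, so a
locus of length L contributes L−k+1 candidate start positions. The
per-locus count of unique starts is `u`; loci with u < 500 (default,
`min_u`) are excluded as too poorly mappable to genotype. Locus GC is
computed over the union of unique k-mer footprints (the mappable
nucleotides), falling back to all unambiguous bases when none exist.
Counting is exact and hash-based — suitable for the desk-scale
references the simulator produces (≤ 5 Mb); genome-scale maps can be
imported through the same BED interval format instead of recomputed.

## Depths and ratios

The observed depth D counts deduplicated, uniquely aligned reads by
their start position only (no fractional overlap weighting), restricted
to frequency-1 positions inside the locus. The expected baseline depth
is E = u·N/G with N the genome-wide uniquely-aligned read count and G
the genome size (2,858,018,193 nt for the human build the default
profile documents, mitochondrion excluded). E normalizes by total
genome size rather than mappable-genome size; any constant factor this
introduces is common to all loci of a sample and is absorbed when the
GC normalization re-centers ratios around 1. The ratio r = D/E has
expectation m/2 at genotype m — 0, 0.5, 1, 1.5, 2 for genotypes 0–4.

## GC normalization

Per sample, raw ratios of ~3,000 copy-number-invariant 10 kb
normalization loci are zero-centered and a cubic smoothing spline
f(gc) is fitted, with the penalty chosen by generalized
cross-validation (`scipy.interpolate.make_smoothing_spline`). Before
fitting, outlier loci are removed by a conservative quartile rule
(outside [Q1 − 3·IQR, Q3 + 3·IQR], quartiles by linear interpolation —
stated so the filter is reproducible bit-for-bit). Large inputs are
reduced to ≤ 200 weighted quantile-bin knots before the GCV search, as
classical smoothing-spline implementations do; this conditions the
generalized cross-validation problem and does not visibly change the
fit at the noise levels involved. The correction is multiplicative,
r_adj = r_raw/(1 + f(gc)): a multiplicative form preserves the m/2
ladder at non-baseline genotypes, which an additive correction would
distort wherever |f| is large. Evaluation outside the training GC
range is clamped to the boundary value (cubic tails diverge). Curves
consume *raw* ratios only; `normalize_depths` refuses a table that
already carries `r_adj`. Samples whose adjusted ratios on the
normalization loci have variance > 0.01 (default `qc_cutoff`) fail QC —
on real data this flags very low coverage.

## Variance model

Observed ratio variance for loci of one length class decomposes as
Var(r) = α·poisson_var + σ²_bg with poisson_var = mean(1/E) over the
class. The calibration dataset subdivides one hundred invariant 50 kb
loci into non-overlapping segments of 1, 1.25, 1.5, 1.75, 2, 2.25, 2.5,
3, 5, 7.5, 10, 20, 30 and 40 kb; the undivided 50 kb locus is the 15th
class. α and σ²_bg come from ordinary least squares of observed on
Poisson variance (slope and intercept); a negative intercept is clamped
to 0 with a warning, since a variance cannot be negative. Statistics
are computed per sample, not pooled across samples — the model is a
per-sample quantity even though its magnitude is similar across
samples. At genotype m the ratio variance used downstream is
σ²_m = α·(m/2)/E2 + σ²_bg (Poisson count variance (m/2)·E2 divided by
E2²); at m = 0 only the background term remains, and a zero total
variance is floored at 1e−30 so the genotype-0 density degenerates to a
near-point-mass rather than an error.

## Genotyping

Stage 1 standardizes r_adj − 1 by the baseline (m = 2) standard
deviation, takes two-sided normal p-values, and applies
Benjamini–Hochberg once across *all* (locus, sample) tests of the run —
a global threshold, not per sample (a per-locus pooling flag exists but
is not default). The CNV rule is strict: q < threshold (default 5%); a
pair exactly at the threshold is not a CNV. Non-significant pairs are
assigned genotype 2 directly, without MAP evaluation — the two-stage
structure prevents the classifier from drifting off baseline on noise.
Stage 2 evaluates Gaussian log-densities at means m/2, m ∈ {0..c_max}
(default c_max = 10, configurable; observed real-data genotypes reach
9), normalizes by log-sum-exp, and takes the MAP under a uniform prior
1/(c_max+1). A trained (e.g. EM) prior was considered and rejected: it
would require training data reflecting the true genotype-frequency
distribution locus by locus. Exact ties resolve to the lower genotype;
output ordering is deterministic (locus, then sample). The LOD score is
log₁₀(p_best/p_second), capped at 300 when the runner-up underflows;
calls with LOD ≤ the threshold (default 0) are reported NA but keep
their posterior summary. A significant pair whose MAP is nonetheless 2
is reported as genotype 2 with its CNV flag kept and a warning — the
conflict is surfaced, never silently overridden in either direction.

## Population summaries

Locus classes are determined solely by the observed genotype multiset:
all 2 → non-variable; ⊆{0,1,2} → bi-allelic deletion; ⊆{2,3,4} →
bi-allelic duplication; anything else multi-allelic. The bi-allelic
duplication decomposition assumes a single-copy-gain allele (2=rr,
3=vr, 4=vv), so any genotype ≥ 5 forces multi-allelic; the strict rule
admits no out-of-range stragglers. Allele counts follow from the
decomposition; the 95% CI on the reference frequency is a Wilson
interval, chosen for its behavior at frequencies near 0 or 1. For
multi-allelic loci the reference frequency is estimated from the
fraction p2 of genotype-2 samples, assumed homozygous reference; under
random mating the allele frequency is sqrt(p2) (default), with the raw
p2 available via a flag since the assumption behind either estimator is
heuristic. Inter-individual difference is the L1 distance between
genotype vectors; the ranked-cumulative curve drops the rarest CNV
frequency class at each step and re-expresses the mean pairwise
difference as % of the full-set mean. Mendelian checks decompose
bi-allelic genotypes into unordered allele pairs and test whether one
allele per parent can produce the child; multi-allelic loci are
rejected as ambiguous. The permutation test redraws group labels
(default 1,000 times, seeded) and reports the two-sided proportion of
permuted |T| ≥ |t|. Boundary substitution replaces a locus with an
external breakpoint interval when both reciprocal-overlap fractions
exceed 0.51, best (largest minimum fraction) candidate winning and
exact ties keeping the original. Concordance between call sets is the
fraction of jointly non-missing cells with exactly identical integers.

## Simulator

The generator realizes precisely the noise decomposition the model
estimates: counts are gamma-Poisson (negative binomial) with mean
λ = (m/2)·E2·(1+gc_bias(gc))·(1+ε) and variance α·λ, with
ε ~ N(0, σ²_bg) truncated at −1 so counts stay non-negative. At the
baseline genotype the resulting ratio variance is exactly
α/E2 + σ²_bg; at other genotypes the background contribution scales as
(m/2)², a property of this multiplicative mechanism — the model only
fixes the variance decomposition at baseline, and all calibration
datasets are baseline loci. α = 1 falls back to plain Poisson; α < 1 is
refused (warned) since a gamma-Poisson mixture cannot under-disperse.
Defaults mirror low-coverage human cohorts: 150 samples, ~3 kb loci at
~67 expected reads/kb (E2 ≈ 200 for 3 kb), α = 2.5 (middle of the 1–4
range seen on real data), σ²_bg = 0.002. The genome fixture
(`simulate_genome`) emits a random ≤ 5 Mb reference with optional exact
duplications (creating genuinely non-unique k-mers), locus intervals,
and per-sample read starts placed on uniquely mappable positions, so
the whole pipeline runs from FASTA to genotype matrix against known
truth; it uses α = 1, the condition under which ≥ 98% exact genotype
recovery at E2 = 200 is the expected operating point (at α = 2.5 the
4-genotype ladder spacing is ~4σ and accuracy sits near 94–96%).
Reads are emitted only inside loci; the genome-wide total N is carried
explicitly in the sample profiles, since reads outside loci influence
nothing downstream.

What the simulator does *not* emulate: read sequences and sequencing
error, alignment artifacts, paired-end inserts, reference mis-assembly,
segmental-duplication paralog cross-mapping beyond exact copies, and
isochore structure (GC strata are sampled directly). Passing tests
therefore demonstrate correctness of the statistical machinery under
its own assumptions, not robustness to every artifact of real
sequencing data.

## Problem sizes and numerical choices

Test and example simulations use cohorts of 10–150 samples and 11–500
loci, a 1 Mb end-to-end genome, and 10,000-draw oracle comparisons —
sizes at which every stage's statistical target (FDR ≤ 5%+3σ on 1,000
null tests, ≥ 95% recall on 627 hemizygous tests, α within ±10% and
σ²_bg within ±50% on the 15-class design, ≥ 98% end-to-end accuracy)
is decidable with seeded determinism. All randomness flows through
`numpy.random.default_rng` with explicit seeds; no global state. BH
correction delegates to statsmodels, Wilson intervals to statsmodels,
spline fitting to scipy — each verified in the test suite against an
independent hand-written oracle (step-up enumeration, closed-form
bound, known-bias recovery).

## Known limitations

Exact k-mer counting in pure Python is the bottleneck for references
beyond a few Mb; real-genome use should import precomputed uniqueness
masks. The z-test assumes normal ratios, accurate for E2 ≳ 50 (verified
by QQ linearity); at very low coverage the discreteness of counts
breaks the approximation before it breaks the MAP step. Chromosome X/Y
loci are processed identically to autosomes; interpreting the male
baseline of 1 is the caller's responsibility. Multi-allelic
allele-frequency estimation is heuristic by construction.
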