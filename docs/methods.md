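# Methods

This note records the models, conventions and numerical choices behind
`peagbs`, and what the synthetic-data generator does and does not emulate.

## Genotype calling

Calls are made per (locus, accession) cell from the two allele read depths.
With total depth *n* and alternate-allele fraction *f* (the "alternate" being
the less-sequenced allele in that cell), the rule is

* *n* = 0 → missing,
* *f* < `hom_max` (default 0.05) → homozygous for the cell's majority allele,
* `hom_max` ≤ *f* < `het_min` (default 0.10) → missing (ambiguous),
* *f* ≥ `het_min` → heterozygous.

Intervals are half-open as written: exactly 5% is ambiguous, exactly 10% is
heterozygous. Two conventions for "alternate" are implemented because the
choice is a genuine degree of freedom in depth-threshold callers: per-cell
(default) and `global-minor`, which anchors *f* to the locus-wise minor
allele with symmetric bands around both homozygous states. Calls are stored
as allele-B dosage {0, 1, 2} with −1 for missing, anchored to the locus's
catalog allele pair; major/minor views and per-locus MAF, call rate and
heterozygosity are derived from the stored calls (MAF from called genotypes,
two allele copies per homozygote, one per heterozygote — never from read
counts).

An intrinsic property of the threshold rule worth knowing: a homozygous cell
of depth *d* is pushed past the heterozygous boundary by ⌈0.1·*d*⌉ miscalled
reads, so at depth 10 a *single* sequencing error (probability ≈ *d*·ε)
produces a heterozygous call. Depth-threshold calling therefore cannot reach
99% concordance below roughly 15–20 reads unless the per-read error rate is
well under 1%. The recovery tests use mean depth 30 with error 0.005.

## Marker filtering and the catalog union

A SNP is retained iff call rate ≥ 0.2, MAF ≥ 0.01 and heterozygosity rate
≤ 0.25. The heterozygosity ceiling exists because a mostly inbred panel
cannot legitimately show high heterozygosity at a real locus; loci that do
are usually collapsed paralogs. Exclusions are attributed to the first
failing rule in the fixed order (call rate, MAF, het rate) so the filter
report is deterministic; the counts reconcile exactly with the input and
output dimensions, and the filter is idempotent.

Tags carrying several SNPs contribute only the lowest-offset SNP that passes
all filters. Two catalogs (64 bp and 80 bp tag dialects) are merged by
locating each short tag inside the long tags with a bounded-edit infix
alignment (edlib): a pair is accepted at ≥ 0.95 identity over ≥ 60 bp
(i.e., up to 3 mismatches over a full 64 bp overlap), the SNP offsets must
coincide under the alignment and the allele pairs must agree. Identity/
overlap thresholds replace database-size-dependent E-values, which are not
reproducible for in-memory tag sets. Ambiguous candidates are resolved by
best identity, then lexicographic id, greedily and deterministically; shared
loci keep the first catalog's genotypes.

## Synthetic collections

The generator emulates the statistical regime of a large inbred germplasm
panel, not any particular genome:

* Per locus, an ancestral allele frequency p ~ Uniform(0.05, 0.95); group
  frequencies are Balding–Nichols draws, Beta(p(1−F)/F, (1−p)(1−F)/F), with
  F the `divergence` parameter (default 0.15; 0 gives identical groups).
* Genotypes are drawn with per-cell autozygosity probability
  1 − h/(2q(1−q)) clipped to [0, 1], so expected heterozygosity equals
  `residual_het_rate` (default 0.005) wherever attainable.
* Read depth is negative binomial (mean 4, shape r = 0.5 — strongly
  overdispersed, as GBS depth is) with tag dropout at rate 0.2. Together
  these give ≈ 47% missing genotypes after calling: 0.2 dropout plus
  0.8 × NB zero mass (≈ 0.33) plus a small ambiguous-fraction contribution.
  This triple (depth 4 / dropout 0.2 / ≈47% missing) is the targeted study
  regime; the three knobs are exposed separately because real missingness
  mixes all three mechanisms in unknown proportions.
* Reads split Binomial(d, ½) for heterozygotes and Binomial(d, ε) to the
  wrong allele for homozygotes (ε = `error_rate`, default 0.01).
* Dual catalogs: a chosen fraction of loci appear in both catalogs, the long
  copy embedding the short tag at a random offset with a configurable number
  of injected substitutions (never at the SNP); the rest split evenly as
  private loci. The ground-truth pairing is returned for recovery tests.
* A binary trait is drawn from a 3-entry penetrance table indexed by
  minor-allele dosage at a designated causal locus (the locus whose realized
  MAF is closest to 0.3, a comfortably common allele for power studies);
  default penetrance (1, 1, 0) makes the trait recessive for the minor
  allele, the classic flower-color pattern.

All randomness flows from one seed through named per-stage streams
(population / depths / catalogs / trait / mask), so identical configurations
are byte-reproducible and stages can be re-drawn independently.

What the generator does **not** emulate: linkage disequilibrium along a map
(loci are exchangeable), restriction-site biology, admixed individuals,
batch/lane effects, or allele-specific bias. Passing tests therefore
demonstrate correctness of the algorithms under the intended noise regime,
not robustness to every artifact of real GBS data.

Deep-coverage recovery checks (caller concordance at mean depth 30) use NB
shape 5 rather than the default 0.5: the default tail is calibrated to the
shallow mean-4 regime, while a deliberately deep validation experiment has
depth concentrated near its mean.

## Private-allele accounting

Groups of unequal size and missingness are made comparable by downsampling
to a common score, an accession contributing 1 − (proportion missing). The
threshold defaults to the smallest group total (generalizing the fixed
published constant to any collection); accessions are accumulated in random
order until the cumulative score enters [T − 0.5, T + 0.5]. If one addition
jumps past the band the ordering is discarded and redrawn (up to 1000
restarts) — the band is only reachable exactly when some prefix lands in it,
and the restart rule makes the accepted-subset distribution well defined
(it matches exhaustive enumeration over orderings; this is tested). An
allele is "observed" in a subset when at least one non-missing call carries
it; missing is never treated as absence, which is the unavoidable convention
when absence cannot be distinguished from non-coverage. Both sides of every
comparison are downsampled each iteration (a `downsample_comparison=False`
escape hatch exists), counts are averaged over 100 iterations by default,
and the focal group is always excluded from its own comparison set.

## Probabilistic PCA

Genotypes are coded as minor-allele dosage (het = 1) and centered on
observed column means. The latent model x = Wz + ε, ε ~ N(0, σ²I) is fit by
EM with missing entries re-imputed from the current reconstruction at each
iteration; the observed-entry reconstruction error is non-increasing and
iteration stops at relative change < 1e-6 (non-convergence is a warning,
never an error). Final axes are taken from an SVD of the completed matrix,
so with complete data the scores coincide exactly with classical PCA;
components are ordered by explained variance with the largest-magnitude
loading of each component made positive.

## Kinship and the mixed-model scan

K = Z′Z / (2 Σ pᵢ(1−pᵢ)) with Z the dosage matrix centered at 2pᵢ and
missing dosages mean-imputed; monomorphic loci are dropped. In a nearly
fully inbred panel the diagonal of K approaches 2 (1 plus an average
inbreeding coefficient near 1), which the tests assert.

The scan treats the binary trait as a 0/1 quantitative response, as the
standard mixed-model GWAS tools do. Variance components are profiled out:
after eigendecomposing K once, the REML likelihood is optimized over
log(σ²_g/σ²_e) ∈ [−10, 10] by bounded scalar search (tolerance 1e-8), with
the σ²_g = 0 boundary checked explicitly. Each SNP is then tested by GLS at
that fixed ratio (P3D/EMMAX); `per_marker_reml=True` re-estimates the ratio
per marker, and `variance_ratio=0` reduces every test exactly to OLS (the
test suite asserts agreement with an independent OLS implementation to
1e-8). SNP dosages are mean-imputed; SNPs monomorphic after the phenotype
NA-drop are reported as NaN and excluded from the Bonferroni denominator m.
Wald p-values use the t distribution with n − p degrees of freedom.

The number of leading PCs in the null model is chosen by BIC =
−2·logL + k·ln(n) with the **ML** likelihood: REML likelihoods are not
comparable across fixed-effect sets, so model selection over PC counts must
use ML. k counts the fixed effects plus both variance components.

## Core selection

Coverage of a subset is the fraction of alleles observed anywhere in the
matrix that are observed within the subset. Selection is a deterministic
greedy set cover — add the eligible accession contributing the most
uncovered alleles, ties broken by higher call rate then lexicographic id —
until the target (default 0.95) is met, followed by one backward pass in
addition order removing accessions whose removal keeps the target met. The
intensity sweep caps the core at ⌈i·n⌉ for i = 0.95, 0.90, …, 0.05 and
returns the smallest core meeting the target (or the best-coverage core,
flagged, if none does). Greedy set cover carries the classical ln(U)+1
approximation guarantee, which the tests check against exhaustive subset
enumeration on small instances. A stochastic replica-search optimizer is
deliberately **not** reproduced: the scientific contract is the coverage
constraint, and a deterministic heuristic makes the selected core exactly
reproducible. Alongside coverage the core reports MAF retention — the
fraction of SNPs whose within-core MAF still clears the collection's 0.01
floor.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so each check has
clear statistical power: the full-scale core-selection run uses 431
accessions × 3000 SNPs; association power uses 20 replicate collections of
400 accessions × 300 SNPs; null calibration uses one 2000-SNP scan
(Kolmogorov–Smirnov) plus 50 replicate null scans against a three-sigma
binomial envelope around the nominal 5% familywise error; downsampling is
validated on a 3-accession group against exhaustive enumeration over
orderings with 10 000 draws.

## Known limitations

* No linkage disequilibrium in the simulator, hence no mapping-resolution
  statements — the association test validates detection, not localization.
* The binary trait is modeled as a linear mixed model, not logistic; this
  matches standard GWAS practice but is an approximation for rare traits.
* Tag pairing assumes substitution-style divergence between catalog copies;
  indel-divergent tag pairs may be missed (edit-distance alignment will
  still find them, but offset coincidence is checked without indel
  remapping).
* The exact column conventions of published HapMap files vary; the reader
  targets the TASSEL-style 11-column dialect this package writes.
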