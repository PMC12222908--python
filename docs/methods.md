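# Methods

This note records the statistical procedures implemented in `hladiv`,
the defaults they run with, and the choices made where several
defensible designs existed.

## Data model and cleaning

Genotypes are unordered allele pairs per subject per locus at 2-field
resolution; names with more fields are truncated, an optional `HLA-`
prefix and expression suffixes (N, L, S, C, A, Q) are stripped.  Rows
sharing a subject ID are resolved in favour of the row with more
non-missing allele cells (tie: first occurrence, logged).  Missingness
is handled per locus: a subject missing one HLA-C allele still
contributes to HLA-A and HLA-B analyses, so locus-level denominators
differ.  No release-aware nomenclature conversion is attempted; input is
assumed current.

## Allele frequencies

Direct counting: each fully typed subject contributes two gene copies;
frequency = count/2n.  Bins are fixed at high ≥ 5%, low < 1%,
intermediate between.  A population-unique allele is one with nonzero
count in exactly one population at a locus; the associated "frequency of
unique alleles (%)" is implemented as the summed relative frequency
those alleles carry in their population, ×100 (the quantity is not
defined more precisely anywhere we could anchor it, so the definition is
recorded in output metadata rather than asserted).

## EM haplotype estimation

For L loci a subject heterozygous at h loci is compatible with
2^(h−1) unordered haplotype pairs.  The observed-data likelihood is
maximised by EM with:

* E-step weights ∝ f(h₁)f(h₂), doubled for heterotypic pairs;
* M-step haplotype frequencies = expected gamete counts / 2n;
* deterministic start at the product of single-locus marginal
  frequencies (reproducible; flat-ridge cases such as a lone double
  heterozygote stay symmetric rather than breaking ties arbitrarily);
* convergence when the relative log-likelihood change < 1e−8
  (max 5000 iterations; non-convergence returns a flagged result).

Three loci use progressive insertion: EM on the first two loci, then
each subject's partial-phase configurations with 2-locus posterior
< 1e−4 are trimmed before the third locus is inserted and the final EM
runs on the surviving expansions.  The threshold is applied to
per-subject phase posteriors at insertion time (the alternative —
cumulative haplotype posteriors — is not what "posterior probability"
most naturally denotes for the insertion step).  Haplotypes ending below
1e−6 are dropped as numerical dust and the rest renormalised.
Monotonicity of the log-likelihood is asserted on every iteration; the
progressive fit is tested for agreement with a brute-force full-space EM
on small fixtures.

A known boundary behaviour: when two loci are perfectly coupled, a
double heterozygote whose allele pair occurs in no other subject leaves
its matched and mismatched phasings likelihood-equivalent, so the EM
solution retains a small amount of mismatched mass and ALD on the
estimated frequencies is slightly below 1 even though the
true-frequency value is exactly 1.

## Exact Hardy–Weinberg test

The null is Levene's distribution of genotype tables conditional on
allele counts.  The sampler is a random-transposition Markov chain on
labelled allele slots (two per subject): the uniform distribution over
slot arrangements marginalises exactly to the conditional distribution
— a table with H heterozygotes has n!/Πn_ij! · 2^H arrangements — so
swapping the contents of two random slots in two random subjects needs
no accept/reject step.  The p-value is the post-dememorisation fraction
of steps whose table probability does not exceed the observed table's.
Defaults: 100 000 dememorisation steps, then 20 batches × 5 000 steps;
the standard error is taken across batch means.  Observed
heterozygosity is the fraction of heterozygous subjects; expected
heterozygosity uses the unbiased correction (2n/(2n−1))(1 − Σp²).

## Ewens–Watterson test

F_obs = Σp².  The null is the Ewens sampling formula conditional on the
number of gene copies 2n and distinct alleles k; conditioning removes
the mutation parameter, leaving partition weights
n!/(Π_j j^{a_j} a_j!).  For 2n ≤ 60 with a small partition space the
null is enumerated exactly; otherwise it is sampled by a Metropolis
walk on labelled allele-count vectors whose stationary weight is
1/Πnᵢ (the labelled-vector form of the same law), with burn-in and
thinning.  Reported: F_exp, sd(F), Fnd = (F_obs − F_exp)/sd(F), and the
lower-tail p-value P(F_null ≤ F_obs) — small p with negative Fnd means
the sample is more even than neutrality predicts, the signature of
balancing selection.  A two-sided variant is available behind a flag.
Sample size is counted in gene copies (2n).

Benjamini–Hochberg adjustment (via statsmodels) is applied per test
type with the family = populations within a locus, matching column-wise
adjusted values in per-locus summary tables; the family choice is
recorded in output metadata.

## Asymmetric LD

With haplotype frequencies h_ab, marginals f_a, f_b, F(A) = Σf_a² and
F(A/B) = Σ_b Σ_a h_ab²/f_b, the directed measure is
W(A/B) = √[(F(A/B) − F(A))/(1 − F(A))] ∈ [0, 1]; it is 0 under
independence, 1 under determinism, equal in both directions and to |r|
for bi-allelic loci.  Pairwise matrices estimate haplotype frequencies
by 2-locus EM per pair (phase is unknown in the intended data);
conditioning alleles with marginal < 1e−12 are dropped to avoid 0/0,
and a monomorphic focal locus yields W = 0 with a warning.  Output
always reports both directions with explicit "focal conditioned on
conditioning" naming.

## Diversity

Shannon −Σp ln p (nats) and Gini–Simpson 1 − Σp² on allele frequency
vectors.  Hellinger distance uses the normalised [0, 1] form, computed
as (1/√2)‖√P − √Q‖₂ on the union of the two allele repertoires (this
form is numerically exact at P = Q).  Similarity is (1 − HD)·100,
stored at full precision with an integer display helper; per-country
average diversity is the uniform mean of (100 − similarity) over loci
and partner populations.

## Rarefaction and extrapolation

The sampling unit is the participant (two gene copies), so curves are
functions of the number of subjects.  Interpolation uses the exact
hypergeometric expectation E[S_n] = Σ_a [1 − C(N−m_a, n)/C(N, n)] over
carrier counts m_a, with a Monte-Carlo subsampler (default 200 reps) as
cross-check.  Extrapolation targets a Chao1-type asymptote on gene-copy
abundances, S_obs + f₁²/(2f₂) (f₂ = 0 fallback f₁(f₁−1)/2), approached
exponentially in added copies; the participant/copy hybrid is recorded
in metadata because no specific estimator is canonical for this
design.  Confidence intervals are percentile bootstrap over 50
resamples of participants.

## Cartography

Population profiles are haplotype relative-frequency vectors restricted
to haplotypes reaching 1% in at least one population (thresholding
before distance computation).  Distances are Euclidean on profiles by
default (Hellinger optional).  Classical MDS double-centres the squared
distances, takes the top-2 eigenpairs and scales by √eigenvalue;
negative eigenvalues are truncated with a warning and the orientation
is canonicalised (first population non-negative on each axis), since
the embedding is otherwise defined only up to rotation/reflection.

## Co-inheritance tables

"Inheritance pattern" is implemented as observed within-locus genotype
co-occurrence — the unordered pair of alleles a subject carries — the
only reading computable from unphased unrelated-subject data.
Marginalising pair counts reproduces allele counts exactly, which is
tested.

## Synthetic cohorts

Subjects are drawn as two haplotypes from explicit 3-locus haplotype
distributions, so LD is encoded exactly and every estimator has a known
truth.  Inbreeding f duplicates one haplotype with probability f;
genotyping error replaces an allele with a random other allele at its
locus at the configured rate.  A single global seed expands to
label-keyed per-population streams, so adding a population leaves
earlier populations' draws unchanged.

The 7-population panel uses cohort sizes (109, 173, 1640, 231, 565,
1765, 661) with nested tribe labels for four populations, geometric
frequency spectra with per-locus decay 0.82/0.88/0.74 and allele pools
of 40/60/30 (so the second locus has the highest effective richness and
the third the least), four private rare alleles per population,
"preferred-partner" LD couplings of 0.8 between loci 2–3 and 0.4 for
locus 1 with locus 2, gamma-jittered per-population spectra, one
out-group with a rank-permuted spectrum and one admixed out-group
(55/45 mixture).  These values were fixed at design time to express the
qualitative structure the panel must carry: skewed spectra, stronger
B–C than A-involving LD, richness ordering B > A > C, and two
progressively more distant out-groups.

What the simulator does **not** emulate: balancing selection (panels are
neutral draws from skewed spectra, so Ewens–Watterson deviates come out
positive, not negative as in real class I HLA data), typing ambiguity,
population substructure within labels beyond sampling noise, and
linkage to untyped loci.  Passing tests on these panels therefore
validate the estimators' correctness and calibration, not any claim
about real cohorts.

## Numerical conventions

Probability ties in exact tests are included with a 1e−9/1e−12 absolute
tolerance; p-value estimates report batch-mean standard errors;
frequencies are kept alongside integer counts to avoid round-trip
drift; all stochastic stages take explicit seeds, and the pipeline
derives per-stage seeds from the run seed.  Problem sizes in the test
suite and acceptance script (chain lengths of 10⁴–10⁵ steps, 500-cohort
calibration runs, the n = 5 144 panel) were chosen to give Monte-Carlo
errors well inside the asserted tolerances.
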