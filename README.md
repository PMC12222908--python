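# hladiv

Population-genetic analysis of Class I HLA (*HLA-A*, *-B*, *-C*) diversity
from multi-locus genotype tables.

HLA class I genes are the most polymorphic loci in the human genome, and
their allele and haplotype frequency landscapes differ sharply between
populations — a first-order problem for T-cell vaccine design, transplant
matching and disease-association studies, where data from one population
cannot simply be extrapolated to another.  `hladiv` is aimed at
immunogenetics analysts who have cohorts of unrelated subjects typed at
2-field resolution (e.g. `A*02:01`) and want the standard battery of
population-genetic summaries, each with a reproducible, seed-controlled
implementation:

* **Allele frequencies** by direct counting, with ≥5% / 1–5% / <1% binning,
  top-allele lists and population-unique allele summaries.
* **Haplotype frequencies** for 2–3 loci by expectation–maximization over
  unphased genotypes, with progressive locus insertion and trimming of
  phase expansions whose posterior falls below 10⁻⁴.
* **Exact Hardy–Weinberg testing** conditional on allele counts: a Markov
  chain of allele transpositions whose stationary law marginalises to
  Levene's conditional distribution, with dememorisation and batch
  standard errors; observed and unbiased expected heterozygosity
  `(2n/(2n−1))(1 − Σp²)`.
* **Ewens–Watterson homozygosity test of neutrality**: F = Σp² against the
  Ewens sampling formula conditional on (2n, k) — exact partition
  enumeration for small samples, Monte-Carlo otherwise — reporting F_exp,
  the normalised deviate Fnd and the lower-tail p-value, with
  Benjamini–Hochberg adjustment across populations.
* **Asymmetric linkage disequilibrium** (ALD): the directional measure
  W(A/B) = √[(F(A/B) − F(A)) / (1 − F(A))] built on conditional
  homozygosity, which reduces to |r| for bi-allelic loci.
* **Diversity indices**: Shannon entropy, Gini–Simpson, and
  Hellinger-distance beta diversity
  HD(P,Q) = √(1 − Σᵢ√(pᵢqᵢ)), reported as similarity percentages
  (1 − HD)·100 and per-country average diversity.
* **Rarefaction and extrapolation** of allelic richness versus number of
  participants (exact hypergeometric interpolation, Chao1-type asymptote,
  bootstrap 95% CIs).
* **Genetic cartography**: classical (Torgerson) MDS of population
  haplotype-frequency profiles (haplotypes at ≥1% in at least one
  population).
* A **synthetic-cohort simulator** that draws subjects from explicit
  3-locus haplotype distributions (optionally with inbreeding and
  genotyping error), so every estimator can be validated against known
  truth — including a 7-population panel emulating a continental survey's
  cohort structure.

## Worked example

```python
import hladiv as h

panel = h.continental_panel(1)          # synthetic 7-population cohort, n=5144

# Hellinger similarity (%) between three East African cohorts at HLA-A
fs = {p: h.count_alleles(panel, "A", country=p)
      for p in ["Kenya", "Rwanda", "Uganda"]}
print(h.similarity_matrix(fs).values.round(1))
#         Kenya  Rwanda  Uganda
# Kenya   100.0    62.4    68.1
# Rwanda   62.4   100.0    71.6
# Uganda   68.1    71.6   100.0

# Ewens-Watterson neutrality test at HLA-A in the Kenyan cohort
res = h.ew_test(h.count_alleles(panel, "A", country="Kenya").counts,
                n_sim=20000, seed=7)
print(f"F_obs={res.f_obs:.4f}  F_exp={res.f_exp:.4f}  "
      f"Fnd={res.fnd:.2f}  p={res.p_value:.4f}")
# F_obs=0.1208  F_exp=0.1425  Fnd=-0.79  p=0.2271

# directed asymmetric LD between the three loci
print(h.ald_matrix(panel, ("A", "B", "C"), country="Kenya").round(3))
```

The similarity matrix says these cohorts share 62–72% of their HLA-A
frequency mass in Hellinger terms; the neutrality test finds observed
homozygosity 0.121 against a conditional-neutral expectation of 0.143
(Fnd = −0.79, not significant); and the ALD table shows the strong
directional B↔C association built into the panel (W(C/B) = 0.87,
W(B/C) = 0.67) against weaker values (0.41–0.57) for pairs involving
HLA-A.

A full report bundle — allele/haplotype tables, HWE and neutrality tables,
similarity matrices, MDS coordinates, rarefaction curves — is produced by
the CLI:

```bash
hladiv simulate --seed 1 --out cohort.csv
hladiv report --input cohort.csv --out-dir out/ --seed 1
```

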