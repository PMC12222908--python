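"""Single-locus population-genetic tests.

* Observed / expected (unbiased) heterozygosity.
* Exact Hardy-Weinberg test conditional on allele counts, estimated with
  the Guo-Thompson Markov chain (random pairwise allele swaps between
  genotypes, Metropolis-accepted under Levene's conditional
  distribution), with dememorisation followed by batch sampling.
* Ewens-Watterson homozygosity test of neutrality: the null is the Ewens
  sampling formula conditional on the number of gene copies 2n and the
  number of distinct alleles k.  Small configuration spaces are
  enumerated exactly over integer partitions; otherwise the null is
  sampled by a Metropolis walk on allele-count vectors (Slatkin's
  Monte-Carlo approach).  The normalised deviate Fnd and the lower-tail
  p-value P(F_null <= F_obs) are reported; small p with negative Fnd
  indicates excess evenness, the signature of balancing selection.
* Benjamini-Hochberg step-up adjustment for multiple testing.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from math import lgamma, log

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeTable

GenotypePair = tuple[str, str]


class MonomorphicLocusError(ValueError):
    """Test undefined: only one allele observed."""


# ---------------------------------------------------------------------------
# heterozygosity


def heterozygosity(pairs: list[GenotypePair]) -> tuple[float, float]:
    """Observed and unbiased expected heterozygosity.

    obs = fraction of heterozygous subjects; exp = (2n/(2n-1)) * (1 - sum p_i^2),
    the sample-size-corrected gene diversity.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    obs = sum(a != b for a, b in pairs) / n
    tally: Counter[str] = Counter()
    for a, b in pairs:
        tally[a] += 1
        tally[b] += 1
    copies = 2 * n
    p = np.array(list(tally.values())) / copies
    exp = (copies / (copies - 1)) * (1.0 - float(np.sum(p**2)))
    return obs, exp


def _pairs_from_table(table: GenotypeTable, locus: str,
                      country: str | None, tribe: str | None) -> list[GenotypePair]:
    rows = table.subset(country=country, tribe=tribe).typed_at(locus)
    return [tuple(sorted((a, b)))
            for a, b in zip(rows[f"{locus}_1"], rows[f"{locus}_2"])]


# ---------------------------------------------------------------------------
# exact HWE test (Guo-Thompson Markov chain)


@dataclass
class HWEResult:
    p_value: float
    se: float
    obs_het: float
    exp_het: float
    n_subjects: int
    n_alleles: int
    dememorization: int
    batches: int
    steps_per_batch: int
    seed: int


def hwe_exact_test(
    pairs: list[GenotypePair],
    dememorization: int = 100_000,
    batches: int = 20,
    steps_per_batch: int = 5_000,
    seed: int = 0,
) -> HWEResult:
    """Markov-chain estimate of the exact conditional HWE p-value.

    The p-value is the null probability, conditional on the observed
    allele counts, of genotype tables no more probable than the observed
    one.  The chain swaps alleles between random slots of two random
    subjects; the uniform distribution over labelled slot arrangements
    marginalises exactly to Levene's conditional distribution over
    genotype tables (a table with H heterozygotes has n!/prod(n_ij!) *
    2^H arrangements), so the transposition walk needs no
    accept/reject step.  After *dememorization* steps the indicator
    {P(table) <= P(observed)} is averaged over *batches* x
    *steps_per_batch* steps, with the standard error taken across batch
    means.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    alleles = sorted({a for p in pairs for a in p})
    k = len(alleles)
    if k < 2:
        raise MonomorphicLocusError("HWE test undefined for a monomorphic locus")
    idx = {a: i for i, a in enumerate(alleles)}
    ga = np.array([idx[min(a, b)] for a, b in pairs], dtype=np.intp)
    gb = np.array([idx[max(a, b)] for a, b in pairs], dtype=np.intp)
    T = np.zeros((k, k), dtype=np.int64)
    for i, j in zip(ga, gb):
        T[i, j] += 1
    het = int(np.sum(ga != gb))
    # relative log-probability: H ln2 - sum log T_ij!
    s = het * math.log(2.0) - float(sum(lgamma(c + 1) for c in T[T > 0]))
    s_obs = s
    tol = 1e-9

    rng = np.random.default_rng(seed)
    log2 = math.log(2.0)
    total_steps = dememorization + batches * steps_per_batch
    u_draws = rng.integers(0, n, size=total_steps)
    v_draws = rng.integers(0, n - 1, size=total_steps)
    slot_draws = rng.integers(0, 4, size=total_steps)

    # slots[i] = the two allele slots of subject i (order carries the
    # arrangement state; the genotype is the sorted pair)
    slots = np.stack([ga.copy(), gb.copy()], axis=1)
    batch_hits = np.zeros(batches, dtype=np.int64)
    for step in range(total_steps):
        u = u_draws[step]
        v = v_draws[step]
        if v >= u:
            v += 1
        su, sv = divmod(int(slot_draws[step]), 2)
        x, y = slots[u, su], slots[v, sv]
        if x != y:
            o1 = (min(slots[u, 0], slots[u, 1]), max(slots[u, 0], slots[u, 1]))
            o2 = (min(slots[v, 0], slots[v, 1]), max(slots[v, 0], slots[v, 1]))
            slots[u, su], slots[v, sv] = y, x
            n1 = (min(slots[u, 0], slots[u, 1]), max(slots[u, 0], slots[u, 1]))
            n2 = (min(slots[v, 0], slots[v, 1]), max(slots[v, 0], slots[v, 1]))
            if o1 != n1 or o2 != n2:
                delta = 0.0
                for (p, q) in (o1, o2):
                    c = T[p, q]
                    delta += log(c)
                    T[p, q] = c - 1
                    if p != q:
                        delta -= log2
                for (p, q) in (n1, n2):
                    c = T[p, q]
                    delta -= log(c + 1)
                    T[p, q] = c + 1
                    if p != q:
                        delta += log2
                s += delta
        if step >= dememorization and s <= s_obs + tol:
            batch_hits[(step - dememorization) // steps_per_batch] += 1

    batch_p = batch_hits / steps_per_batch
    p = float(batch_p.mean())
    se = float(batch_p.std(ddof=1) / math.sqrt(batches)) if batches > 1 else float("nan")
    obs_het, exp_het = heterozygosity(pairs)
    return HWEResult(p, se, obs_het, exp_het, n, k,
                     dememorization, batches, steps_per_batch, seed)


# ---------------------------------------------------------------------------
# Ewens-Watterson homozygosity test of neutrality


@dataclass
class EWResult:
    f_obs: float
    f_exp: float
    f_sd: float
    fnd: float
    p_value: float
    se: float
    n_copies: int
    n_alleles: int
    method: str  # "exact" or "monte-carlo"
    seed: int | None = None


@lru_cache(maxsize=None)
def _n_partitions(n: int, k: int, max_part: int | None = None) -> int:
    """Number of partitions of n into exactly k parts with parts <= max_part."""
    if max_part is None:
        max_part = n
    if k == 0:
        return 1 if n == 0 else 0
    if n < k:
        return 0
    total = 0
    for largest in range(min(n - k + 1, max_part), 0, -1):
        total += _n_partitions(n - largest, k - 1, largest)
    return total


def _partitions(n: int, k: int, max_part: int | None = None):
    """Yield partitions of n into exactly k parts, non-increasing order."""
    if max_part is None:
        max_part = n
    if k == 1:
        if n <= max_part:
            yield (n,)
        return
    for largest in range(min(n - k + 1, max_part), 0, -1):
        for rest in _partitions(n - largest, k - 1, largest):
            yield (largest,) + rest


def ewens_null_exact(n_copies: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null over allele configurations under the Ewens sampling
    formula conditional on (n_copies, k).

    Returns (F values, probabilities), one entry per integer partition of
    n_copies into k parts; P(partition) is proportional to
    n! / (prod_j j^{a_j} a_j!) with a_j the number of parts of size j.
    """
    logws, fs = [], []
    for part in _partitions(n_copies, k):
        mult = Counter(part)
        lw = lgamma(n_copies + 1) - sum(
            a * log(j) + lgamma(a + 1) for j, a in mult.items()
        )
        logws.append(lw)
        fs.append(sum((c / n_copies) ** 2 for c in part))
    logws = np.array(logws)
    w = np.exp(logws - logws.max())
    return np.array(fs), w / w.sum()


def _ewens_null_sample(
    n_copies: int, k: int, n_sim: int, seed: int, burnin: int = 2_000, thin: int = 5
) -> np.ndarray:
    """Metropolis sample of F under the conditional Ewens null.

    The walk acts on labelled allele-count vectors (n_1..n_k), each >= 1,
    whose stationary weight is proportional to 1/prod n_i; one copy at a
    time is moved between two random classes.
    """
    rng = np.random.default_rng(seed)
    counts = np.ones(k, dtype=np.int64)
    remainder = n_copies - k
    # spread the remainder roughly geometrically for a warm start
    for _ in range(remainder):
        counts[rng.integers(0, k)] += 1
    total_steps = burnin + n_sim * thin
    i_draws = rng.integers(0, k, size=total_steps)
    j_draws = rng.integers(0, k - 1, size=total_steps)
    u_draws = rng.random(size=total_steps)
    sumsq = float(np.sum(counts.astype(float) ** 2))
    out = np.empty(n_sim)
    m = 0
    for step in range(total_steps):
        i = i_draws[step]
        j = j_draws[step]
        if j >= i:
            j += 1
        ni, nj = counts[i], counts[j]
        if ni > 1:
            # weight ratio (1/prod new)/(1/prod old) = ni*nj/((ni-1)*(nj+1))
            ratio = (ni * nj) / ((ni - 1) * (nj + 1))
            if ratio >= 1.0 or u_draws[step] < ratio:
                counts[i] -= 1
                counts[j] += 1
                sumsq += 2.0 * (nj - ni + 1)
        if step >= burnin and (step - burnin) % thin == 0:
            out[m] = sumsq
            m += 1
    return out[:m] / (n_copies * n_copies)


#: enumerate exactly when the partition space is at most this large
EXACT_PARTITION_LIMIT = 20_000


def ew_test(
    allele_counts: dict[str, int] | list[int],
    n_sim: int = 100_000,
    seed: int = 0,
    two_sided: bool = False,
) -> EWResult:
    """Ewens-Watterson homozygosity test of neutrality.

    F_obs = sum p_i^2 over observed allele frequencies.  The null
    distribution of F conditional on (2n, k) is enumerated exactly when
    the partition space is small and otherwise sampled by Monte Carlo.
    The default p-value is the lower tail P(F_null <= F_obs); the
    two-sided doubling of the smaller tail is available behind a flag.
    """
    counts = (list(allele_counts.values())
              if isinstance(allele_counts, dict) else list(allele_counts))
    counts = [int(c) for c in counts if c > 0]
    k = len(counts)
    n_copies = sum(counts)
    if k < 2:
        raise MonomorphicLocusError("EW test undefined for a monomorphic locus")
    f_obs = sum((c / n_copies) ** 2 for c in counts)

    if n_copies <= 60 and _n_partitions(n_copies, k) <= EXACT_PARTITION_LIMIT:
        fs, probs = ewens_null_exact(n_copies, k)
        f_exp = float(np.dot(fs, probs))
        f_sd = float(math.sqrt(max(np.dot((fs - f_exp) ** 2, probs), 0.0)))
        lower = float(probs[fs <= f_obs + 1e-12].sum())
        upper = float(probs[fs >= f_obs - 1e-12].sum())
        se = 0.0
        method = "exact"
    else:
        fs = _ewens_null_sample(n_copies, k, n_sim, seed)
        f_exp = float(fs.mean())
        f_sd = float(fs.std(ddof=1))
        lower = float(np.mean(fs <= f_obs + 1e-12))
        upper = float(np.mean(fs >= f_obs - 1e-12))
        se = float(math.sqrt(max(lower * (1 - lower), 1e-12) / len(fs)))
        method = "monte-carlo"
    p = min(1.0, 2 * min(lower, upper)) if two_sided else lower
    fnd = (f_obs - f_exp) / f_sd if f_sd > 0 else float("nan")
    return EWResult(f_obs, f_exp, f_sd, fnd, p, se, n_copies, k, method, seed)


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(arr, method="fdr_bh")
    return list(adj)


# ---------------------------------------------------------------------------
# Table-style summaries across populations


def hwe_table(
    table: GenotypeTable,
    loci: tuple[str, ...],
    populations: list[str],
    seed: int = 0,
    by: str = "country",
    **chain_kwargs,
) -> pd.DataFrame:
    """HWE statistics per (population, locus), BH-adjusted per locus
    across populations (the adjustment family of the per-locus columns)."""
    rows = []
    root = np.random.SeedSequence(seed)
    for locus in loci:
        for pi, pop in enumerate(populations):
            sel = {"country": pop} if by == "country" else {"tribe": pop}
            pairs = _pairs_from_table(table, locus, sel.get("country"), sel.get("tribe"))
            sub_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
            res = hwe_exact_test(pairs, seed=sub_seed, **chain_kwargs)
            rows.append(
                {"population": pop, "locus": locus, "n_subjects": res.n_subjects,
                 "obs_het": res.obs_het, "exp_het": res.exp_het,
                 "p_value": res.p_value, "mc_se": res.se, "seed": sub_seed}
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for locus in loci:
        m = out["locus"] == locus
        out.loc[m, "p_adj"] = bh_adjust(list(out.loc[m, "p_value"]))
    return out


def ew_table(
    table: GenotypeTable,
    loci: tuple[str, ...],
    populations: list[str],
    seed: int = 0,
    by: str = "country",
    n_sim: int = 100_000,
) -> pd.DataFrame:
    """Ewens-Watterson statistics per (population, locus) with per-locus
    BH adjustment across populations."""
    rows = []
    root = np.random.SeedSequence(seed)
    for locus in loci:
        for pop in populations:
            sel = {"country": pop} if by == "country" else {"tribe": pop}
            pairs = _pairs_from_table(table, locus, sel.get("country"), sel.get("tribe"))
            tally: Counter[str] = Counter()
            for a, b in pairs:
                tally[a] += 1
                tally[b] += 1
            sub_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
            res = ew_test(dict(tally), n_sim=n_sim, seed=sub_seed)
            rows.append(
                {"population": pop, "locus": locus, "n_copies": res.n_copies,
                 "k_alleles": res.n_alleles, "f_obs": res.f_obs,
                 "f_exp": res.f_exp, "fnd": res.fnd, "p_value": res.p_value,
                 "mc_se": res.se, "method": res.method, "seed": sub_seed}
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for locus in loci:
        m = out["locus"] == locus
        out.loc[m, "p_adj"] = bh_adjust(list(out.loc[m, "p_value"]))
    return out
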