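"""Alpha and beta diversity of allele frequency distributions.

Alpha diversity within a population: Shannon entropy (-sum p ln p, in
nats) and the Gini-Simpson index (1 - sum p^2, the probability that two
randomly drawn gene copies are different alleles).  Beta diversity
between populations: the Hellinger distance

    HD(P, Q) = sqrt(1 - sum_i sqrt(p_i q_i))

computed on the union of the two allele repertoires (absent allele ->
frequency 0), with range [0, 1].  Similarity is reported as
(1 - HD) * 100 percent, and a country's average diversity against a set
of partner populations is the mean of (100 - similarity%) over loci and
partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frequencies import AlleleFrequencySet

_DIST_TOL = 1e-9


def _validate(freqs) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size == 0 or np.any(p < -1e-12):
        raise ValueError("frequencies must be a non-empty 1-D non-negative array")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    return np.clip(p, 0.0, None)


def shannon(freqs) -> float:
    """Shannon entropy in nats; 0 ln 0 taken as 0."""
    p = _validate(freqs)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def gini_simpson(freqs) -> float:
    """Probability that two random gene copies are different alleles."""
    p = _validate(freqs)
    return float(1.0 - np.sum(p**2))


def hellinger(p_set: AlleleFrequencySet, q_set: AlleleFrequencySet) -> float:
    """Hellinger distance between two populations' allele distributions
    at the same locus, aligned on the union of observed alleles."""
    if p_set.locus != q_set.locus:
        raise ValueError(f"locus mismatch: {p_set.locus} vs {q_set.locus}")
    p, q = p_set.frequencies, q_set.frequencies
    alleles = sorted(set(p) | set(q))
    pv = np.array([p.get(a, 0.0) for a in alleles])
    qv = np.array([q.get(a, 0.0) for a in alleles])
    return hellinger_arrays(pv, qv)


def hellinger_arrays(p, q) -> float:
    """Hellinger distance between two aligned frequency vectors."""
    pv = _validate(p)
    qv = _validate(q)
    if pv.shape != qv.shape:
        raise ValueError("aligned distributions must have equal length")
    # the (1/sqrt 2)||sqrt p - sqrt q|| form is numerically exact at p = q,
    # unlike sqrt(1 - Bhattacharyya)
    d = float(np.linalg.norm(np.sqrt(pv) - np.sqrt(qv)) / np.sqrt(2.0))
    return min(d, 1.0)


@dataclass
class SimilarityMatrix:
    """Population x population Hellinger similarity percentages at one locus."""

    locus: str
    populations: list[str]
    values: pd.DataFrame  # square, in [0, 100], diagonal 100

    def similarity(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])

    def rounded(self) -> pd.DataFrame:
        """Integer display form (full precision kept in ``values``)."""
        return self.values.round(0).astype(int)


def similarity_matrix(freq_sets: dict[str, AlleleFrequencySet]) -> SimilarityMatrix:
    """Pairwise similarity% = (1 - HD) * 100 across >= 2 populations."""
    if len(freq_sets) < 2:
        raise ValueError("need at least two populations")
    pops = list(freq_sets)
    locus = freq_sets[pops[0]].locus
    m = np.full((len(pops), len(pops)), 100.0)
    for i, a in enumerate(pops):
        for j in range(i + 1, len(pops)):
            sim = (1.0 - hellinger(freq_sets[a], freq_sets[pops[j]])) * 100.0
            m[i, j] = m[j, i] = sim
    return SimilarityMatrix(locus, pops, pd.DataFrame(m, index=pops, columns=pops))


def average_diversity(
    matrices: list[SimilarityMatrix], focal: str, partners: list[str]
) -> float:
    """Mean percentage diversity (100 - similarity%) of *focal* against
    *partners*, averaged uniformly over loci and partners."""
    if not partners:
        raise ValueError("partner set is empty")
    vals = []
    for sm in matrices:
        for p in partners:
            if p == focal:
                continue
            vals.append(100.0 - sm.similarity(focal, p))
    if not vals:
        raise ValueError("no usable (locus, partner) combinations")
    return float(np.mean(vals))


def alpha_diversity_table(freq_sets: list[AlleleFrequencySet]) -> pd.DataFrame:
    """Per-(population, locus) richness, Shannon and Gini-Simpson table."""
    rows = []
    for fs in freq_sets:
        p = fs.entries["frequency"].to_numpy()
        rows.append(
            {"population": fs.population, "locus": fs.locus,
             "n_subjects": fs.n_subjects, "richness": fs.richness,
             "shannon": shannon(p), "gini_simpson": gini_simpson(p)}
        )
    return pd.DataFrame(rows)
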