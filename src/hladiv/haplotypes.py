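"""Multi-locus haplotype frequency estimation by EM with progressive insertion.

Phase is unobserved in unrelated-subject genotype data: a subject
heterozygous at h of the requested loci is compatible with 2**(h-1)
unordered haplotype pairs.  The EM algorithm iterates between assigning
posterior weights to each compatible pair (E-step, proportional to the
product of the two haplotype frequencies, doubled for heterotypic pairs)
and re-estimating frequencies from the weighted gamete counts (M-step).

For three loci the haplotype space is pruned by progressive insertion:
EM is first run on the first two loci, then each subject's partial-phase
configurations with posterior probability below a threshold (default
1e-4) are discarded before the third locus is inserted and the final EM
is run on the surviving expansions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 5000
DEFAULT_POSTERIOR_THRESHOLD = 1e-4
DUST_THRESHOLD = 1e-6

Haplotype = tuple[str, ...]


def haplotype_label(hap: Haplotype) -> str:
    """Render a haplotype in tilde notation, e.g. ``A*30:01~B*42:01``."""
    return "~".join(hap)


@dataclass
class HaplotypeFrequencySet:
    """Estimated haplotype frequencies with EM diagnostics."""

    loci: tuple[str, ...]
    haplotypes: list[Haplotype]
    frequencies: np.ndarray
    log_likelihood: float = math.nan
    iterations: int = 0
    converged: bool = True
    trim_threshold: float = DEFAULT_POSTERIOR_THRESHOLD
    n_subjects: int = 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(self.frequencies < -1e-12):
            raise ValueError("negative haplotype frequency")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies do not sum to 1")

    @property
    def entries(self) -> pd.DataFrame:
        order = np.argsort(-self.frequencies, kind="stable")
        return pd.DataFrame(
            {
                "loci": ":".join(self.loci),
                "haplotype": [haplotype_label(self.haplotypes[i]) for i in order],
                "frequency": self.frequencies[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )

    def frequency_of(self, hap: Haplotype) -> float:
        try:
            return float(self.frequencies[self.haplotypes.index(hap)])
        except ValueError:
            return 0.0

    def as_dict(self) -> dict[Haplotype, float]:
        return {h: float(f) for h, f in zip(self.haplotypes, self.frequencies)}

    def marginal(self, locus: str) -> dict[str, float]:
        """Marginal allele frequencies at one of the constituent loci."""
        j = self.loci.index(locus)
        out: dict[str, float] = {}
        for hap, f in zip(self.haplotypes, self.frequencies):
            out[hap[j]] = out.get(hap[j], 0.0) + float(f)
        return out


# ---------------------------------------------------------------------------
# phase enumeration


def _subject_genotypes(table: GenotypeTable, loci: tuple[str, ...]) -> list[tuple]:
    """Per-subject multi-locus genotypes (sorted allele pair per locus),
    restricted to subjects fully typed at every requested locus."""
    d = table.data
    mask = np.ones(len(d), dtype=bool)
    for l in loci:
        mask &= d[f"{l}_1"].notna().to_numpy() & d[f"{l}_2"].notna().to_numpy()
    rows = d[mask]
    out = []
    for _, row in rows.iterrows():
        out.append(
            tuple(tuple(sorted((row[f"{l}_1"], row[f"{l}_2"]))) for l in loci)
        )
    return out


def enumerate_phases(genotype: tuple) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs compatible with a multi-locus genotype.

    The orientation at the first heterozygous locus is fixed to avoid
    listing each unordered pair twice.
    """
    het = [i for i, (a, b) in enumerate(genotype) if a != b]
    if not het:
        hap = tuple(a for a, _ in genotype)
        return [(hap, hap)]
    free = het[1:]
    phases = []
    for bits in itertools.product((0, 1), repeat=len(free)):
        h1, h2 = [], []
        flip = dict(zip(free, bits))
        for i, (a, b) in enumerate(genotype):
            if i not in het:
                h1.append(a)
                h2.append(a)
            elif i == het[0] or not flip.get(i, 0):
                h1.append(a)
                h2.append(b)
            else:
                h1.append(b)
                h2.append(a)
        phases.append((tuple(h1), tuple(h2)))
    return phases


# ---------------------------------------------------------------------------
# EM core (vectorised over phase expansions)


class _Expansion:
    """Flat arrays of candidate phase pairs across distinct genotypes."""

    def __init__(self, phase_lists: list[list[tuple[Haplotype, Haplotype]]],
                 counts: np.ndarray):
        hap_index: dict[Haplotype, int] = {}
        h1, h2, gidx = [], [], []
        for g, phases in enumerate(phase_lists):
            for a, b in phases:
                h1.append(hap_index.setdefault(a, len(hap_index)))
                h2.append(hap_index.setdefault(b, len(hap_index)))
                gidx.append(g)
        self.haplotypes: list[Haplotype] = list(hap_index)
        self.h1 = np.array(h1, dtype=np.intp)
        self.h2 = np.array(h2, dtype=np.intp)
        self.gidx = np.array(gidx, dtype=np.intp)
        self.mult = np.where(self.h1 == self.h2, 1.0, 2.0)
        self.counts = np.asarray(counts, dtype=float)
        self.n_genotypes = len(phase_lists)


def _run_em(exp: _Expansion, f0: np.ndarray, tol: float, max_iter: int
            ) -> tuple[np.ndarray, float, int, bool]:
    """EM iterations; returns (frequencies, loglik, iterations, converged).

    The observed-data log-likelihood is checked to be non-decreasing at
    every iteration (up to round-off), a structural property of EM.
    """
    f = np.asarray(f0, dtype=float)
    f = f / f.sum()
    n = exp.counts.sum()
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = exp.mult * f[exp.h1] * f[exp.h2]
        tot = np.bincount(exp.gidx, weights=w, minlength=exp.n_genotypes)
        if np.any(tot <= 0):
            # a genotype lost all its phases (can only happen with a
            # degenerate start); fall back to uniform over its phases
            bad = tot <= 0
            w = np.where(bad[exp.gidx], exp.mult, w)
            tot = np.bincount(exp.gidx, weights=w, minlength=exp.n_genotypes)
        ll = float(np.dot(exp.counts, np.log(tot)))
        if ll < prev_ll - 1e-9 * max(1.0, abs(prev_ll)):
            raise AssertionError(
                f"EM log-likelihood decreased: {prev_ll} -> {ll}"
            )
        post = w / tot[exp.gidx] * exp.counts[exp.gidx]
        f_new = (
            np.bincount(exp.h1, weights=post, minlength=len(f))
            + np.bincount(exp.h2, weights=post, minlength=len(f))
        ) / (2.0 * n)
        if prev_ll > -np.inf and abs(ll - prev_ll) <= tol * max(1.0, abs(ll)):
            f = f_new
            converged = True
            break
        f = f_new
        prev_ll = ll
    w = exp.mult * f[exp.h1] * f[exp.h2]
    tot = np.bincount(exp.gidx, weights=w, minlength=exp.n_genotypes)
    ll = float(np.dot(exp.counts, np.log(np.maximum(tot, 1e-300))))
    return f, ll, it, converged


def _marginal_start(exp: _Expansion, n_loci: int) -> np.ndarray:
    """Deterministic start: product of single-locus marginal allele
    frequencies computed by direct counting from the genotype data."""
    marg: list[dict[str, float]] = [dict() for _ in range(n_loci)]
    # gene-copy counts per locus via the phase expansions would double
    # count; recover them from each genotype's first listed phase, which
    # contains each subject's two alleles exactly once per locus.
    first_phase = {}
    for row, g in enumerate(exp.gidx):
        if g not in first_phase:
            first_phase[g] = row
    total = exp.counts.sum()
    for g, row in first_phase.items():
        c = exp.counts[g]
        for hap_id in (exp.h1[row], exp.h2[row]):
            hap = exp.haplotypes[hap_id]
            for j, allele in enumerate(hap):
                marg[j][allele] = marg[j].get(allele, 0.0) + c
    for j in range(n_loci):
        for a in marg[j]:
            marg[j][a] /= 2.0 * total
    f0 = np.array(
        [np.prod([marg[j][h[j]] for j in range(n_loci)]) for h in exp.haplotypes]
    )
    return f0 / f0.sum()


def _finalise(exp: _Expansion, f: np.ndarray, ll: float, it: int, conv: bool,
              loci: tuple[str, ...], threshold: float, n_subjects: int
              ) -> HaplotypeFrequencySet:
    keep = f >= DUST_THRESHOLD
    haps = [h for h, k in zip(exp.haplotypes, keep) if k]
    freqs = f[keep]
    freqs = freqs / freqs.sum()
    order = sorted(range(len(haps)), key=lambda i: haps[i])
    return HaplotypeFrequencySet(
        loci=loci,
        haplotypes=[haps[i] for i in order],
        frequencies=freqs[order],
        log_likelihood=ll,
        iterations=it,
        converged=conv,
        trim_threshold=threshold,
        n_subjects=n_subjects,
    )


def em_haplotypes(
    table: GenotypeTable,
    loci: tuple[str, ...],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
    country: str | None = None,
    tribe: str | None = None,
) -> HaplotypeFrequencySet:
    """Estimate haplotype frequencies for 2 or 3 loci.

    Two loci: plain EM over the full phase expansion from the
    product-of-marginals start.  Three loci: EM on the first two loci,
    then progressive insertion of the third — partial-phase expansions
    with 2-locus posterior below *posterior_threshold* are trimmed before
    the final EM.  Haplotypes ending below 1e-6 are dropped as numerical
    dust and the remainder renormalised.
    """
    loci = tuple(loci)
    if not 2 <= len(loci) <= 3:
        raise ValueError("em_haplotypes supports 2 or 3 loci")
    sub = table.subset(country=country, tribe=tribe)
    genos = _subject_genotypes(sub, loci)
    if not genos:
        raise ValueError(f"no subjects fully typed at {loci}")
    from collections import Counter

    geno_counts = Counter(genos)
    distinct = list(geno_counts)
    counts = np.array([geno_counts[g] for g in distinct], dtype=float)
    n_subjects = int(counts.sum())

    if len(loci) == 2:
        exp = _Expansion([enumerate_phases(g) for g in distinct], counts)
        f0 = _marginal_start(exp, 2)
        f, ll, it, conv = _run_em(exp, f0, tol, max_iter)
        return _finalise(exp, f, ll, it, conv, loci, posterior_threshold, n_subjects)

    # --- progressive insertion for 3 loci ------------------------------
    pair_fit = em_haplotypes(
        table, loci[:2], tol=tol, max_iter=max_iter,
        posterior_threshold=posterior_threshold, country=country, tribe=tribe,
    )
    pair_freqs = pair_fit.as_dict()
    third_marg: dict[str, float] = {}
    for g, c in geno_counts.items():
        for allele in g[2]:
            third_marg[allele] = third_marg.get(allele, 0.0) + c
    z = sum(third_marg.values())
    third_marg = {a: v / z for a, v in third_marg.items()}

    phase_lists = []
    seed_freq: dict[Haplotype, float] = {}
    for g in distinct:
        partial_phases = enumerate_phases(g[:2])
        weights = np.array(
            [(1.0 if p == q else 2.0) * pair_freqs.get(p, 0.0) * pair_freqs.get(q, 0.0)
             for p, q in partial_phases]
        )
        if weights.sum() > 0:
            post = weights / weights.sum()
            kept = [pp for pp, w in zip(partial_phases, post)
                    if w >= posterior_threshold]
        else:
            kept = partial_phases
        if not kept:  # never trim a subject to nothing
            kept = [partial_phases[int(np.argmax(weights))]]
        c1, c2 = g[2]
        expanded = set()
        for p, q in kept:
            expanded.add(tuple(sorted((p + (c1,), q + (c2,)))))
            expanded.add(tuple(sorted((p + (c2,), q + (c1,)))))
        phases = [tuple(e) for e in expanded]
        phase_lists.append(phases)
        for h1, h2 in phases:
            for h in (h1, h2):
                if h not in seed_freq:
                    seed_freq[h] = (
                        pair_freqs.get(h[:2], DUST_THRESHOLD) * third_marg[h[2]]
                    )

    exp = _Expansion(phase_lists, counts)
    f0 = np.array([seed_freq[h] for h in exp.haplotypes])
    f0 = np.maximum(f0, 1e-12)
    f0 = f0 / f0.sum()
    f, ll, it, conv = _run_em(exp, f0, tol, max_iter)
    return _finalise(exp, f, ll, it, conv, loci, posterior_threshold, n_subjects)


def phase_posteriors(
    genotype: tuple, freq_set: HaplotypeFrequencySet
) -> list[tuple[tuple[Haplotype, Haplotype], float]]:
    """Posterior probability of each phase configuration of a subject.

    *genotype* is a tuple of sorted allele pairs, one per locus of
    *freq_set*.  Posteriors are proportional to f(h1)*f(h2), doubled for
    heterotypic pairs, and sum to 1.  Raises if the subject carries an
    allele absent from the frequency set's repertoire.
    """
    if len(genotype) != len(freq_set.loci):
        raise ValueError("genotype/loci arity mismatch")
    for j, locus in enumerate(freq_set.loci):
        known = freq_set.marginal(locus)
        for allele in genotype[j]:
            if allele not in known:
                raise ValueError(f"allele {allele} absent from haplotype set at {locus}")
    freqs = freq_set.as_dict()
    phases = enumerate_phases(genotype)
    w = np.array(
        [(1.0 if a == b else 2.0) * freqs.get(a, 0.0) * freqs.get(b, 0.0)
         for a, b in phases]
    )
    if w.sum() <= 0:
        w = np.ones(len(phases))
    w = w / w.sum()
    return list(zip(phases, w))
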