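"""Rarefaction and extrapolation of allelic richness versus sample size.

The sampling unit is the participant (two gene copies).  Interpolation
uses the exact hypergeometric expectation of the number of distinct
alleles in a random subsample of participants (a Monte-Carlo version is
available as a cross-check).  Extrapolation beyond the observed sample
uses a Chao1-type asymptotic richness estimator on gene-copy abundances
(singletons f1 and doubletons f2), with percentile confidence intervals
from bootstrap resampling of participants.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeTable

DEFAULT_BOOTSTRAP = 50
DEFAULT_REPS = 200


@dataclass
class RarefactionCurve:
    """Richness estimates over participant depths, with 95% bounds for
    the extrapolated part."""

    population: str
    locus: str
    n_participants: int
    table: pd.DataFrame  # depth, mode, estimate, ci_low, ci_high


def _carrier_matrix(table: GenotypeTable, locus: str,
                    country: str | None, tribe: str | None):
    """Per-participant allele pairs and per-allele carrier counts."""
    rows = table.subset(country=country, tribe=tribe).typed_at(locus)
    pairs = [tuple(sorted((a, b)))
             for a, b in zip(rows[f"{locus}_1"], rows[f"{locus}_2"])]
    if not pairs:
        raise ValueError(f"no fully typed subjects at {locus}")
    carriers: Counter[str] = Counter()
    for a, b in pairs:
        carriers[a] += 1
        if b != a:
            carriers[b] += 1
    return pairs, carriers


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy_exact(pairs: list[tuple[str, str]], depth: int) -> float:
    """Hypergeometric expectation of distinct alleles among *depth*
    participants drawn without replacement:
    E[S] = sum_a [1 - C(N - m_a, n) / C(N, n)] with m_a carriers of a."""
    N = len(pairs)
    if not 1 <= depth <= N:
        raise ValueError(f"depth {depth} out of range 1..{N}")
    carriers: Counter[str] = Counter()
    for a, b in pairs:
        carriers[a] += 1
        if b != a:
            carriers[b] += 1
    total = 0.0
    for m in carriers.values():
        if N - m >= depth:
            total += 1.0 - np.exp(_log_comb(N - m, depth) - _log_comb(N, depth))
        else:
            total += 1.0
    return float(total)


def rarefy_mc(pairs: list[tuple[str, str]], depth: int, reps: int, seed: int
              ) -> tuple[float, float]:
    """Monte-Carlo subsampling mean richness and its standard error."""
    N = len(pairs)
    if not 1 <= depth <= N:
        raise ValueError(f"depth {depth} out of range 1..{N}")
    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    for r in range(reps):
        idx = rng.choice(N, size=depth, replace=False)
        seen = set()
        for i in idx:
            seen.add(pairs[i][0])
            seen.add(pairs[i][1])
        vals[r] = len(seen)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(reps))


def chao1(abundances: list[int] | np.ndarray) -> float:
    """Chao1 asymptotic richness from abundance counts.

    S_est = S_obs + f1^2 / (2 f2); when f2 = 0 the f1(f1-1)/2 fallback is
    used.  With no singletons the asymptote equals the observed richness.
    """
    ab = np.asarray(abundances)
    ab = ab[ab > 0]
    s_obs = len(ab)
    f1 = int(np.sum(ab == 1))
    f2 = int(np.sum(ab == 2))
    if f1 == 0:
        return float(s_obs)
    if f2 > 0:
        return float(s_obs + f1 * f1 / (2.0 * f2))
    return float(s_obs + f1 * (f1 - 1) / 2.0)


def _extrapolate_point(pairs: list[tuple[str, str]], depth: int) -> float:
    """Expected richness at *depth* participants (> N) via the
    abundance-based extrapolation toward the Chao1 asymptote."""
    N = len(pairs)
    copies: Counter[str] = Counter()
    for a, b in pairs:
        copies[a] += 1
        copies[b] += 1
    ab = np.array(list(copies.values()))
    s_obs = len(ab)
    n_c = 2 * N
    f1 = int(np.sum(ab == 1))
    f0 = chao1(ab) - s_obs
    if f0 <= 0 or f1 == 0:
        return float(s_obs)
    m_extra_copies = 2 * (depth - N)
    return float(
        s_obs + f0 * (1.0 - (1.0 - f1 / (n_c * f0 + f1)) ** m_extra_copies)
    )


def rarefy(
    table: GenotypeTable,
    locus: str,
    country: str | None = None,
    tribe: str | None = None,
    depths: list[int] | None = None,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    method: str = "exact",
    population_label: str | None = None,
) -> RarefactionCurve:
    """Interpolated rarefaction curve over participant depths 1..N.

    ``method="exact"`` uses the hypergeometric closed form (default);
    ``method="mc"`` averages *reps* random subsamples without
    replacement.
    """
    pairs, _ = _carrier_matrix(table, locus, country, tribe)
    N = len(pairs)
    if depths is None:
        depths = list(range(1, N + 1))
    rows = []
    rng = np.random.default_rng(seed)
    for d in depths:
        if method == "exact":
            est = rarefy_exact(pairs, d)
        elif method == "mc":
            est, _ = rarefy_mc(pairs, d, reps, int(rng.integers(2**31)))
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"depth": d, "mode": "interpolated", "estimate": est,
                     "ci_low": np.nan, "ci_high": np.nan})
    label = population_label or (tribe or country or "all")
    return RarefactionCurve(label, locus, N, pd.DataFrame(rows))


def extrapolate(
    table: GenotypeTable,
    locus: str,
    depths: list[int],
    country: str | None = None,
    tribe: str | None = None,
    bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
    population_label: str | None = None,
) -> RarefactionCurve:
    """Extrapolated richness beyond the observed sample with bootstrap
    95% percentile confidence intervals (default 50 resamples)."""
    pairs, _ = _carrier_matrix(table, locus, country, tribe)
    N = len(pairs)
    if any(d <= N for d in depths):
        raise ValueError(f"extrapolation depths must exceed N = {N}")
    copies: Counter[str] = Counter()
    for a, b in pairs:
        copies[a] += 1
        copies[b] += 1
    ab = np.array(list(copies.values()))
    degenerate = int(np.sum(ab == 1)) == 0 and int(np.sum(ab == 2)) == 0
    if degenerate:
        warnings.warn("no singletons or doubletons: asymptote = observed "
                      "richness, degenerate CI")
    rng = np.random.default_rng(seed)
    boot = np.empty((bootstrap, len(depths)))
    for b in range(bootstrap):
        idx = rng.integers(0, N, size=N)
        resampled = [pairs[i] for i in idx]
        for j, d in enumerate(depths):
            boot[b, j] = _extrapolate_point(resampled, d)
    rows = []
    for j, d in enumerate(depths):
        rows.append(
            {"depth": d, "mode": "extrapolated",
             "estimate": _extrapolate_point(pairs, d),
             "ci_low": float(np.percentile(boot[:, j], 2.5)),
             "ci_high": float(np.percentile(boot[:, j], 97.5))}
        )
    label = population_label or (tribe or country or "all")
    return RarefactionCurve(label, locus, N, pd.DataFrame(rows))


def rarefaction_curve(
    table: GenotypeTable,
    locus: str,
    country: str | None = None,
    tribe: str | None = None,
    extrapolate_to: int | None = None,
    n_depths: int = 40,
    bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
    population_label: str | None = None,
) -> RarefactionCurve:
    """Combined interpolated + extrapolated curve on a depth grid."""
    pairs, _ = _carrier_matrix(table, locus, country, tribe)
    N = len(pairs)
    interp_depths = sorted(set(np.linspace(1, N, min(n_depths, N)).astype(int)))
    curve = rarefy(table, locus, country=country, tribe=tribe,
                   depths=interp_depths, seed=seed,
                   population_label=population_label)
    if extrapolate_to is not None and extrapolate_to > N:
        extra_depths = sorted(
            set(np.linspace(N + 1, extrapolate_to,
                            min(10, extrapolate_to - N)).astype(int))
        )
        extra = extrapolate(table, locus, extra_depths, country=country,
                            tribe=tribe, bootstrap=bootstrap, seed=seed,
                            population_label=population_label)
        curve.table = pd.concat([curve.table, extra.table], ignore_index=True)
    return curve
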