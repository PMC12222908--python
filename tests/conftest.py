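"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-derivations (full
enumeration, dict-based EM) kept separate from the library code they
check.
"""

from __future__ import annotations

import itertools
from collections import Counter
from math import lgamma, log, exp

import numpy as np
import pandas as pd
import pytest

from hladiv import GenotypeTable, PopulationSpec, SimulationConfig, \
    continental_panel, simulate_population


# ---------------------------------------------------------------------------
# table builders


def make_table(rows: list[dict]) -> GenotypeTable:
    cols = ["pid", "country", "tribe"] + [f"{l}_{i}" for l in "ABC" for i in (1, 2)]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = pd.NA
    return GenotypeTable(df[cols])


def simulate_cohort(hap_freqs: dict, n: int, seed: int, label: str = "X",
                    f: float = 0.0, error_rate: float = 0.0) -> GenotypeTable:
    spec = PopulationSpec(label, n, hap_freqs, inbreeding_f=f,
                          error_rate=error_rate)
    return simulate_population(SimulationConfig([spec], seed=seed))


def random_hap_freqs(rng: np.random.Generator, k_a=3, k_b=4, k_c=3) -> dict:
    """Random full-support 3-locus haplotype distribution."""
    names = {
        0: [f"A*{i+1:02d}:01" for i in range(k_a)],
        1: [f"B*{i+1:02d}:01" for i in range(k_b)],
        2: [f"C*{i+1:02d}:01" for i in range(k_c)],
    }
    haps = list(itertools.product(names[0], names[1], names[2]))
    w = rng.dirichlet(np.ones(len(haps)) * 1.2)
    return dict(zip(haps, w))


@pytest.fixture(scope="session")
def panel() -> GenotypeTable:
    """The 7-population synthetic panel (seed fixed for the session)."""
    return continental_panel(1)


# ---------------------------------------------------------------------------
# oracle: exact conditional HWE p by full table enumeration


def enumerate_hwe_p(pairs: list[tuple[str, str]]) -> float:
    """Exact conditional HWE p-value by enumerating every genotype table
    compatible with the observed allele counts (Levene distribution)."""
    alleles = sorted({a for p in pairs for a in p})
    k = len(alleles)
    idx = {a: i for i, a in enumerate(alleles)}
    m = [0] * k
    obs = Counter()
    for a, b in pairs:
        m[idx[a]] += 1
        m[idx[b]] += 1
        obs[tuple(sorted((idx[a], idx[b])))] += 1
    n = len(pairs)
    cells = [(i, j) for i in range(k) for j in range(i, k)]

    def log_prob(table: dict) -> float:
        h = sum(c for (i, j), c in table.items() if i != j)
        lp = lgamma(n + 1) + sum(lgamma(x + 1) for x in m) + h * log(2.0) \
            - lgamma(2 * n + 1) - sum(lgamma(c + 1) for c in table.values())
        return lp

    tables = []

    def recurse(ci: int, remaining: list[int], used: int, table: dict):
        if ci == len(cells):
            if used == n and all(r == 0 for r in remaining):
                tables.append(dict(table))
            return
        i, j = cells[ci]
        if i == j:
            cmax = min(remaining[i] // 2, n - used)
        else:
            cmax = min(remaining[i], remaining[j], n - used)
        for c in range(cmax + 1):
            remaining[i] -= c * (2 if i == j else 1)
            if i != j:
                remaining[j] -= c
            if c:
                table[(i, j)] = c
            recurse(ci + 1, remaining, used + c, table)
            remaining[i] += c * (2 if i == j else 1)
            if i != j:
                remaining[j] += c
            table.pop((i, j), None)

    recurse(0, m, 0, {})
    lp_obs = log_prob(obs)
    total = 0.0
    p = 0.0
    for t in tables:
        lp = log_prob(t)
        total += exp(lp)
        if lp <= lp_obs + 1e-9:
            p += exp(lp)
    assert abs(total - 1.0) < 1e-9, f"enumeration probabilities sum to {total}"
    return p


# ---------------------------------------------------------------------------
# oracle: brute-force EM over the full haplotype space


def brute_force_em(genotypes: list[tuple], tol: float = 1e-12,
                   max_iter: int = 20000) -> tuple[dict, float]:
    """Plain dict-based EM over all phase pairs of all loci at once (no
    progressive insertion, no trimming), from the product-of-marginals
    start.  Returns (frequencies, final log-likelihood)."""
    n = len(genotypes)
    n_loci = len(genotypes[0])

    def phases(g):
        out = set()
        for orient in itertools.product((0, 1), repeat=n_loci):
            h1 = tuple(g[j][orient[j]] for j in range(n_loci))
            h2 = tuple(g[j][1 - orient[j]] for j in range(n_loci))
            out.add(tuple(sorted((h1, h2))))
        return sorted(out)

    phase_lists = [phases(g) for g in genotypes]
    marg = [Counter() for _ in range(n_loci)]
    for g in genotypes:
        for j in range(n_loci):
            marg[j][g[j][0]] += 1
            marg[j][g[j][1]] += 1
    hap_set = sorted({h for pl in phase_lists for pair in pl for h in pair})
    f = {h: np.prod([marg[j][h[j]] / (2 * n) for j in range(n_loci)])
         for h in hap_set}
    z = sum(f.values())
    f = {h: v / z for h, v in f.items()}
    prev = -np.inf
    for _ in range(max_iter):
        new = dict.fromkeys(f, 0.0)
        ll = 0.0
        for pl in phase_lists:
            ws = [(2.0 if a != b else 1.0) * f[a] * f[b] for a, b in pl]
            tot = sum(ws)
            ll += log(tot)
            for (a, b), w in zip(pl, ws):
                share = w / tot
                new[a] += share
                new[b] += share
        f = {h: v / (2 * n) for h, v in new.items()}
        if abs(ll - prev) <= tol * max(1.0, abs(ll)):
            break
        prev = ll
    return f, ll


def genotypes_from_table(table: GenotypeTable, loci: tuple[str, ...]) -> list[tuple]:
    out = []
    for _, row in table.data.iterrows():
        if all(pd.notna(row[f"{l}_{i}"]) for l in loci for i in (1, 2)):
            out.append(tuple(
                tuple(sorted((row[f"{l}_1"], row[f"{l}_2"]))) for l in loci
            ))
    return out


# ---------------------------------------------------------------------------
# oracle: Ewens null by direct partition enumeration (independent of the
# implementation's enumeration: builds partitions via a different recursion)


def ewens_null_brute(n_copies: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-part partitions of n_copies with Ewens conditional weights
    n! / (prod_j j^{a_j} a_j!), via accumulate-and-filter recursion."""
    results = []

    def parts(n, kk, cap):
        if kk == 0:
            if n == 0:
                yield ()
            return
        for first in range(min(cap, n - kk + 1), 0, -1):
            for rest in parts(n - first, kk - 1, first):
                yield (first,) + rest

    ws, fs = [], []
    for p in parts(n_copies, k, n_copies):
        mult = Counter(p)
        lw = lgamma(n_copies + 1)
        for size, a in mult.items():
            lw -= a * log(size) + lgamma(a + 1)
        ws.append(lw)
        fs.append(sum((c / n_copies) ** 2 for c in p))
    ws = np.exp(np.array(ws) - max(ws))
    return np.array(fs), ws / ws.sum()
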