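"""Synthetic multi-locus HLA genotype cohorts with controlled structure.

Cohorts are drawn from explicit 3-locus haplotype frequency
distributions: each subject receives two haplotypes (or, with
inbreeding coefficient f, a single duplicated haplotype with
probability f), so linkage disequilibrium is encoded exactly in the
haplotype distribution and every downstream estimator has a known
truth.  An optional genotyping-error perturbation replaces an allele
with a random other allele at its locus.

:func:`continental_panel` builds a 7-population panel emulating the
structure of a continental HLA survey: cohort sizes (109, 173, 1640,
231, 565, 1765, 661), skewed allele frequency spectra with more alleles
at the second locus than the first and third, stronger coupling between
loci 2-3 than for pairs involving locus 1, nested tribe labels for four
populations, and two out-group populations with shifted spectra.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import LOCI, GenotypeTable

Haplotype = tuple[str, str, str]


@dataclass
class PopulationSpec:
    """One population's generating parameters."""

    label: str
    n_subjects: int
    haplotype_freqs: dict[Haplotype, float]
    tribes: list[tuple[str, int]] = field(default_factory=list)
    inbreeding_f: float = 0.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.label}: haplotype frequencies sum to {total}")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding coefficient must lie in [0, 1]")
        if sum(n for _, n in self.tribes) > self.n_subjects:
            raise ValueError(f"{self.label}: tribe sizes exceed population size")


@dataclass
class SimulationConfig:
    populations: list[PopulationSpec]
    seed: int = 0
    loci: tuple[str, ...] = LOCI


def _population_rng(seed: int, label: str) -> np.random.Generator:
    """Independent stream per population, stable under adding populations."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), zlib.crc32(label.encode())))
    )


def simulate_population(config: SimulationConfig) -> GenotypeTable:
    """Draw a genotype cohort from explicit haplotype distributions."""
    records = []
    for spec in config.populations:
        rng = _population_rng(config.seed, spec.label)
        haps = list(spec.haplotype_freqs)
        probs = np.array([spec.haplotype_freqs[h] for h in haps])
        probs = probs / probs.sum()
        n = spec.n_subjects
        h1_idx = rng.choice(len(haps), size=n, p=probs)
        h2_idx = rng.choice(len(haps), size=n, p=probs)
        if spec.inbreeding_f > 0:
            auto = rng.random(n) < spec.inbreeding_f
            h2_idx[auto] = h1_idx[auto]
        tribe_labels: list[object] = []
        for tribe, cnt in spec.tribes:
            tribe_labels.extend([tribe] * cnt)
        tribe_labels.extend([pd.NA] * (n - len(tribe_labels)))

        alleles_by_locus = None
        if spec.error_rate > 0:
            alleles_by_locus = [sorted({h[j] for h in haps}) for j in range(3)]
        for i in range(n):
            ha, hb = haps[h1_idx[i]], haps[h2_idx[i]]
            rec = {"pid": f"{spec.label}-{i:05d}", "country": spec.label,
                   "tribe": tribe_labels[i]}
            for j, locus in enumerate(config.loci):
                a, b = ha[j], hb[j]
                if spec.error_rate > 0:
                    pool = alleles_by_locus[j]
                    if rng.random() < spec.error_rate and len(pool) > 1:
                        a = pool[rng.integers(len(pool) - 1)]
                    if rng.random() < spec.error_rate and len(pool) > 1:
                        b = pool[rng.integers(len(pool) - 1)]
                rec[f"{locus}_1"], rec[f"{locus}_2"] = sorted((a, b))
            records.append(rec)
    cols = ["pid", "country", "tribe"] + [f"{l}_{i}" for l in config.loci for i in (1, 2)]
    return GenotypeTable(pd.DataFrame(records, columns=cols), config.loci)


# ---------------------------------------------------------------------------
# spectrum and haplotype-distribution construction


def allele_names(locus: str, k: int, start: int = 1) -> list[str]:
    """Plausible 2-field names: <locus>*<group>:<protein>."""
    return [f"{locus}*{(start + i - 1) % 99 + 1:02d}:{(start + i - 1) // 99 + 1:02d}"
            for i in range(k)]


def skewed_spectrum(k: int, decay: float = 0.82, jitter: float = 0.3,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Geometric-decay frequency spectrum with multiplicative gamma
    jitter: a few alleles above 5% and a long tail below 1%, the shape
    typical of class I HLA loci."""
    w = decay ** np.arange(k)
    if rng is not None and jitter > 0:
        w = w * rng.gamma(1.0 / jitter, jitter, size=k)
    return w / w.sum()


def coupled_haplotype_freqs(
    freq_a: dict[str, float],
    freq_b: dict[str, float],
    freq_c: dict[str, float],
    coupling_ab: float,
    coupling_bc: float,
    rng: np.random.Generator,
) -> dict[Haplotype, float]:
    """Build a 3-locus haplotype distribution with controlled LD.

    The second locus is drawn from its marginal; the first and third are
    conditionally independent given the second, each equal to a
    "preferred partner" of the second-locus allele with probability
    equal to the coupling, and an independent marginal draw otherwise.
    Coupling 0 gives linkage equilibrium; coupling 1 makes the second
    locus determine the partner locus.
    """
    if not (0 <= coupling_ab <= 1 and 0 <= coupling_bc <= 1):
        raise ValueError("couplings must lie in [0, 1]")
    a_alleles, a_p = zip(*sorted(freq_a.items()))
    c_alleles, c_p = zip(*sorted(freq_c.items()))
    a_p, c_p = np.array(a_p), np.array(c_p)
    pref_a = {b: a_alleles[rng.choice(len(a_alleles), p=a_p)] for b in freq_b}
    pref_c = {b: c_alleles[rng.choice(len(c_alleles), p=c_p)] for b in freq_b}
    haps: dict[Haplotype, float] = {}
    for b, pb in freq_b.items():
        for i, a in enumerate(a_alleles):
            pa = (1 - coupling_ab) * a_p[i] + (coupling_ab if a == pref_a[b] else 0.0)
            if pa == 0.0:
                continue
            for j, c in enumerate(c_alleles):
                pc = (1 - coupling_bc) * c_p[j] + (coupling_bc if c == pref_c[b] else 0.0)
                f = pb * pa * pc
                if f > 0:
                    haps[(a, b, c)] = haps.get((a, b, c), 0.0) + f
    total = sum(haps.values())
    return {h: f / total for h, f in haps.items()}


# ---------------------------------------------------------------------------
# panel emulating a continental survey's cohort structure

PANEL_SIZES = {
    "Kenya": 109, "Rwanda": 173, "SouthAfrica": 1640, "Uganda": 231,
    "Zambia": 565, "EUAM": 1765, "AFAM": 661,
}
PANEL_TRIBES = {
    "Kenya": [("Kikuyu", 25), ("Luhya", 21)],
    "Uganda": [("Muganda", 134), ("Munyankole", 25), ("Munyarwanda", 26)],
    "Zambia": [("Bemba", 142), ("Chewa", 63), ("Lozi", 23), ("Ngoni", 44),
               ("Nsenga", 70), ("Tonga", 29), ("Tumbuka", 29)],
    "SouthAfrica": [("Zulu", 1624)],
}
#: allele pool sizes per locus: the second locus is the most polymorphic,
#: the third the least
PANEL_POOL = {"A": 40, "B": 60, "C": 30}
#: spectrum decay per locus: flatter (closer to 1) means more even
#: frequencies and higher effective richness, so B > A > C
PANEL_DECAY = {"A": 0.82, "B": 0.88, "C": 0.74}
#: LD couplings: strong between loci 2-3, moderate for pairs involving locus 1
PANEL_COUPLING_BC = 0.8
PANEL_COUPLING_AB = 0.4


def continental_panel_config(seed: int = 0) -> SimulationConfig:
    """Generating parameters of the 7-population panel (see module docstring)."""
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xD1CE)))
    base = {l: skewed_spectrum(k, decay=PANEL_DECAY[l])
            for l, k in PANEL_POOL.items()}
    # the two out-groups share a shifted spectrum: permute allele ranks so
    # different alleles are common, mirroring a genetically distant pool
    perm = {l: rng.permutation(k) for l, k in PANEL_POOL.items()}
    populations = []
    african = ["Kenya", "Rwanda", "SouthAfrica", "Uganda", "Zambia"]
    for label, n in PANEL_SIZES.items():
        prng = _population_rng(seed, label + ":spectrum")
        freqs = {}
        for locus, k in PANEL_POOL.items():
            names = allele_names(locus, k)
            if label == "EUAM":
                w = base[locus][perm[locus]]
            elif label == "AFAM":
                w = 0.55 * base[locus] + 0.45 * base[locus][perm[locus]]
            else:
                w = base[locus]
            # population-specific jitter differentiates the cohorts
            w = w * prng.gamma(6.0, 1 / 6.0, size=k)
            # a handful of population-private rare alleles
            w = np.concatenate([w / w.sum() * 0.985,
                                np.full(4, 0.015 / 4)])
            start = k + 1 + 4 * (african + ["EUAM", "AFAM"]).index(label)
            names = names + allele_names(locus, 4, start=start)
            freqs[locus] = dict(zip(names, w / w.sum()))
        hap_freqs = coupled_haplotype_freqs(
            freqs["A"], freqs["B"], freqs["C"],
            PANEL_COUPLING_AB, PANEL_COUPLING_BC, prng,
        )
        populations.append(
            PopulationSpec(label, n, hap_freqs, tribes=PANEL_TRIBES.get(label, []))
        )
    return SimulationConfig(populations, seed=seed)


def continental_panel(seed: int = 0) -> GenotypeTable:
    """Simulate the 7-population panel."""
    return simulate_population(continental_panel_config(seed))
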