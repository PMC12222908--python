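"""Synthetic cohort generator: frequency recovery, inbreeding,
determinism and panel structure."""

import numpy as np
import pytest
from scipy import stats

from hladiv import PopulationSpec, SimulationConfig, count_alleles, \
    coupled_haplotype_freqs, heterozygosity, continental_panel, \
    simulate_population, skewed_spectrum
from hladiv.simulate import PANEL_SIZES, PANEL_TRIBES, allele_names
from conftest import random_hap_freqs, simulate_cohort


def test_full_inbreeding_makes_every_subject_homozygous():
    rng = np.random.default_rng(1)
    t = simulate_cohort(random_hap_freqs(rng), n=50, seed=2, f=1.0)
    for l in "ABC":
        assert (t.data[f"{l}_1"] == t.data[f"{l}_2"]).all()


def test_outbred_cohort_is_in_hwe():
    """With f = 0, per-locus genotype proportions match Hardy-Weinberg
    expectations (chi-square on pooled genotype classes)."""
    rng = np.random.default_rng(2)
    t = simulate_cohort(random_hap_freqs(rng, 3, 3, 3), n=2000, seed=8)
    fs = count_alleles(t, "A", country="X")
    alleles = list(fs.frequencies)
    p = np.array([fs.frequencies[a] for a in alleles])
    from collections import Counter
    obs = Counter(tuple(sorted((a, b)))
                  for a, b in zip(t.data["A_1"], t.data["A_2"]))
    classes, expected, observed = [], [], []
    for i, a in enumerate(alleles):
        for j in range(i, len(alleles)):
            b = alleles[j]
            e = 2000 * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
            if e >= 5:
                expected.append(e)
                observed.append(obs.get(tuple(sorted((a, b))), 0))
    expected = np.array(expected) * sum(observed) / sum(expected)
    chi2 = float(np.sum((np.array(observed) - expected) ** 2 / expected))
    assert chi2 < stats.chi2.ppf(0.999, df=len(expected) - 1)


def test_allele_frequency_recovery():
    """Empirical allele frequencies converge to the configured ones
    (within 3 binomial standard errors)."""
    rng = np.random.default_rng(3)
    hf = random_hap_freqs(rng, 4, 4, 4)
    n = 1500
    t = simulate_cohort(hf, n=n, seed=9)
    truth: dict[str, float] = {}
    for h, f in hf.items():
        truth[h[1]] = truth.get(h[1], 0.0) + f
    est = count_alleles(t, "B", country="X").frequencies
    for allele, p in truth.items():
        tol = 3 * np.sqrt(p * (1 - p) / (2 * n))
        assert est.get(allele, 0.0) == pytest.approx(p, abs=max(tol, 1e-3))


def test_heterozygosity_decreases_with_inbreeding():
    rng = np.random.default_rng(4)
    hf = random_hap_freqs(rng, 4, 4, 4)
    obs = []
    for f in (0.0, 0.25, 0.5, 1.0):
        t = simulate_cohort(hf, n=800, seed=10, f=f)
        pairs = [tuple(sorted((a, b)))
                 for a, b in zip(t.data["A_1"], t.data["A_2"])]
        obs.append(heterozygosity(pairs)[0])
    assert obs[0] > obs[1] > obs[2] > obs[3] == 0.0


def test_genotyping_error_perturbs_at_configured_rate():
    hf = {("A*01:01", "B*01:01", "C*01:01"): 0.5,
          ("A*02:01", "B*02:01", "C*02:01"): 0.5}
    t = simulate_cohort(hf, n=1000, seed=11, error_rate=0.0)
    t_err = simulate_cohort(hf, n=1000, seed=11, error_rate=0.05)
    changed = (t.data[[c for c in t.data.columns if "_" in c]]
               != t_err.data[[c for c in t_err.data.columns if "_" in c]])
    rate = changed.to_numpy().mean()
    assert 0.01 < rate < 0.12  # ~5% per allele cell, some swaps collide


def test_determinism_and_stream_independence():
    rng = np.random.default_rng(5)
    hf = random_hap_freqs(rng)
    a1 = simulate_cohort(hf, n=30, seed=12, label="P1").data
    a2 = simulate_cohort(hf, n=30, seed=12, label="P1").data
    assert a1.equals(a2)
    # adding a second population must not perturb the first one's draws
    both = simulate_population(SimulationConfig(
        [PopulationSpec("P1", 30, hf), PopulationSpec("P2", 30, hf)], seed=12))
    assert both.data[both.data["country"] == "P1"].reset_index(drop=True).equals(a1)


def test_coupling_zero_gives_product_distribution():
    rng = np.random.default_rng(6)
    fa = dict(zip(allele_names("A", 3), skewed_spectrum(3)))
    fb = dict(zip(allele_names("B", 4), skewed_spectrum(4)))
    fc = dict(zip(allele_names("C", 3), skewed_spectrum(3)))
    hf = coupled_haplotype_freqs(fa, fb, fc, 0.0, 0.0, rng)
    for (a, b, c), f in hf.items():
        assert f == pytest.approx(fa[a] * fb[b] * fc[c], rel=1e-9)


def test_panel_sizes_and_tribes(panel):
    counts = panel.data["country"].value_counts().to_dict()
    assert counts == PANEL_SIZES
    for country, tribes in PANEL_TRIBES.items():
        sub = panel.data[panel.data["country"] == country]
        for tribe, n in tribes:
            assert (sub["tribe"] == tribe).sum() == n


def test_panel_locus_richness_ordering(panel):
    """More alleles at the second locus than the third at equal n."""
    for country in ("SouthAfrica", "EUAM"):
        rich = {l: count_alleles(panel, l, country=country).richness
                for l in "ABC"}
        assert rich["B"] > rich["C"]


def test_panel_skewed_spectrum(panel):
    """Few alleles at >= 5%, long tail below 1%."""
    fs = count_alleles(panel, "B", country="SouthAfrica")
    freqs = np.array(list(fs.frequencies.values()))
    assert (freqs >= 0.05).sum() <= 10
    assert (freqs < 0.01).sum() > len(freqs) / 3
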