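"""EM haplotype frequency estimation: worked fixed points, brute-force
equivalence and parameter recovery."""

import numpy as np
import pytest

from hladiv import em_haplotypes, enumerate_phases, haplotype_label, \
    phase_posteriors
from conftest import brute_force_em, genotypes_from_table, make_table, \
    random_hap_freqs, simulate_cohort


def _two_locus_table(rows):
    return make_table([
        {"pid": str(i), "country": "X", "A_1": a1, "A_2": a2,
         "B_1": b1, "B_2": b2}
        for i, (a1, a2, b1, b2) in enumerate(rows)
    ])


def test_em_hand_fixed_point():
    """One double homozygote + one double heterozygote: the likelihood
    maximum puts 0.75 on the shared haplotype and 0.25 on its partner."""
    t = _two_locus_table([
        ("A*01:01", "A*01:01", "B*01:01", "B*01:01"),
        ("A*01:01", "A*02:01", "B*01:01", "B*02:01"),
    ])
    fit = em_haplotypes(t, ("A", "B"))
    freqs = fit.as_dict()
    assert freqs[("A*01:01", "B*01:01")] == pytest.approx(0.75, abs=1e-6)
    assert freqs[("A*02:01", "B*02:01")] == pytest.approx(0.25, abs=1e-6)
    assert fit.converged


def test_em_symmetric_ridge_stays_symmetric():
    """A single double heterozygote gives a flat likelihood ridge; the
    symmetric deterministic start keeps all four haplotypes at 0.25."""
    t = _two_locus_table([("A*01:01", "A*02:01", "B*01:01", "B*02:01")])
    fit = em_haplotypes(t, ("A", "B"))
    assert np.allclose(fit.frequencies, 0.25)


def test_em_phase_unambiguous_equals_gamete_counting():
    """When every subject is homozygous at >= 1 locus there is no latent
    phase and EM equals direct gamete counting."""
    t = _two_locus_table([
        ("A*01:01", "A*01:01", "B*01:01", "B*02:01"),
        ("A*02:01", "A*02:01", "B*01:01", "B*01:01"),
        ("A*01:01", "A*02:01", "B*03:01", "B*03:01"),
    ])
    fit = em_haplotypes(t, ("A", "B"))
    freqs = fit.as_dict()
    # gametes: (01,01),(01,02) | (02,01)x2 | (01,03),(02,03)
    assert freqs[("A*01:01", "B*01:01")] == pytest.approx(1 / 6, abs=1e-9)
    assert freqs[("A*02:01", "B*01:01")] == pytest.approx(2 / 6, abs=1e-9)
    assert freqs[("A*01:01", "B*03:01")] == pytest.approx(1 / 6, abs=1e-9)


@pytest.mark.parametrize("loci", [("A", "B"), ("A", "B", "C")])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_em_matches_brute_force(loci, seed):
    """Final log-likelihood and frequencies agree with a dict-based EM
    over the full haplotype space (no insertion, no trimming)."""
    rng = np.random.default_rng(seed)
    t = simulate_cohort(random_hap_freqs(rng, 3, 4, 3), n=60, seed=100 + seed)
    fit = em_haplotypes(t, loci, tol=1e-12, max_iter=20000)
    genos = genotypes_from_table(t, loci)
    brute_f, brute_ll = brute_force_em(genos)
    assert fit.log_likelihood == pytest.approx(brute_ll, abs=1e-6)
    for hap, freq in brute_f.items():
        assert fit.frequency_of(hap) == pytest.approx(freq, abs=1e-4)


def test_em_recovers_true_frequencies():
    """3-locus frequencies simulated at n=500 are recovered with mean
    absolute error < 0.02 on haplotypes with true frequency >= 1%."""
    rng = np.random.default_rng(42)
    truth = random_hap_freqs(rng, 4, 5, 4)
    t = simulate_cohort(truth, n=500, seed=77)
    fit = em_haplotypes(t, ("A", "B", "C"))
    errs = [abs(fit.frequency_of(h) - f) for h, f in truth.items() if f >= 0.01]
    assert errs and float(np.mean(errs)) < 0.02


def test_enumerate_phases_counts():
    g2het = (("a1", "a2"), ("b1", "b2"))
    assert len(enumerate_phases(g2het)) == 2
    g3het = (("a1", "a2"), ("b1", "b2"), ("c1", "c2"))
    assert len(enumerate_phases(g3het)) == 4
    homo = (("a1", "a1"), ("b1", "b1"))
    assert enumerate_phases(homo) == [(("a1", "b1"), ("a1", "b1"))]


def test_phase_posteriors():
    t = _two_locus_table([
        ("A*01:01", "A*01:01", "B*01:01", "B*01:01"),
        ("A*01:01", "A*02:01", "B*01:01", "B*02:01"),
    ])
    fit = em_haplotypes(t, ("A", "B"))
    homo = (("A*01:01", "A*01:01"), ("B*01:01", "B*01:01"))
    [(_, post)] = phase_posteriors(homo, fit)
    assert post == pytest.approx(1.0)
    dh = (("A*01:01", "A*02:01"), ("B*01:01", "B*02:01"))
    posts = dict(phase_posteriors(dh, fit))
    cis = (("A*01:01", "B*01:01"), ("A*02:01", "B*02:01"))
    assert posts[cis] == pytest.approx(1.0, abs=1e-6)  # 0-frequency trans phase
    assert sum(posts.values()) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        phase_posteriors((("A*09:09", "A*09:09"), ("B*01:01", "B*01:01")), fit)


def test_haplotype_label_tilde_notation():
    assert haplotype_label(("A*30:01", "B*42:01", "C*17:01")) == \
        "A*30:01~B*42:01~C*17:01"


def test_em_errors_without_fully_typed_subjects():
    t = make_table([{"pid": "1", "country": "X",
                     "A_1": "A*01:01", "A_2": "A*01:01"}])
    with pytest.raises(ValueError):
        em_haplotypes(t, ("A", "B"))
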