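"""Heterozygosity, exact HWE chain, Ewens-Watterson neutrality test and
Benjamini-Hochberg adjustment."""

import numpy as np
import pytest

from hladiv import MonomorphicLocusError, bh_adjust, ew_test, \
    ewens_null_exact, heterozygosity, hwe_exact_test
from hladiv.locus_tests import _ewens_null_sample
from conftest import enumerate_hwe_p, ewens_null_brute


# ---------------------------------------------------------------------------
# heterozygosity


def test_heterozygosity_hand_example():
    obs, exp = heterozygosity([("A", "a"), ("A", "a")])
    assert obs == 1.0
    assert exp == pytest.approx(4 / 3 * 0.5)


def test_heterozygosity_monomorphic_and_errors():
    obs, exp = heterozygosity([("A", "A"), ("A", "A")])
    assert obs == 0.0 and exp == 0.0
    with pytest.raises(ValueError):
        heterozygosity([("A", "a")])


def test_obs_het_tracks_exp_het_under_hwe():
    rng = np.random.default_rng(3)
    p = np.array([0.4, 0.3, 0.2, 0.1])
    g = rng.choice(4, size=(2000, 2), p=p)
    pairs = [tuple(sorted((f"x{a}", f"x{b}"))) for a, b in g]
    obs, exp = heterozygosity(pairs)
    assert obs == pytest.approx(exp, abs=0.03)


# ---------------------------------------------------------------------------
# HWE exact test


def test_hwe_two_allele_exact_case():
    """Allele counts A:2, a:2 with observed {AA, aa}: Levene gives the
    observed table probability 1/3, the {Aa,Aa} table 2/3, so p = 1/3."""
    res = hwe_exact_test([("A", "A"), ("a", "a")], dememorization=2000,
                         batches=10, steps_per_batch=2000, seed=5)
    assert res.p_value == pytest.approx(1 / 3, abs=3 * res.se)
    assert enumerate_hwe_p([("A", "A"), ("a", "a")]) == pytest.approx(1 / 3)


def test_hwe_most_probable_table_gives_p_one():
    res = hwe_exact_test([("A", "a"), ("A", "a")], dememorization=1000,
                         batches=5, steps_per_batch=1000, seed=5)
    assert res.p_value == 1.0


@pytest.mark.parametrize("seed", [0, 1])
def test_hwe_chain_matches_enumeration(seed):
    """MC p agrees with the full-enumeration conditional p on a 3-allele
    n=20 fixture within 3 MC standard errors."""
    rng = np.random.default_rng(seed)
    g = rng.choice(3, size=(20, 2), p=[0.5, 0.3, 0.2])
    pairs = [tuple(sorted((f"a{x}", f"a{y}"))) for x, y in g]
    exact = enumerate_hwe_p(pairs)
    res = hwe_exact_test(pairs, dememorization=20000, batches=20,
                         steps_per_batch=2000, seed=99)
    assert res.p_value == pytest.approx(exact, abs=max(3 * res.se, 1e-3))


def test_hwe_invariant_to_allele_relabeling():
    rng = np.random.default_rng(4)
    g = rng.choice(3, size=(30, 2), p=[0.5, 0.3, 0.2])
    pairs = [tuple(sorted((f"a{x}", f"a{y}"))) for x, y in g]
    relabel = {"a0": "z9", "a1": "q5", "a2": "m1"}
    pairs2 = [tuple(sorted((relabel[a], relabel[b]))) for a, b in pairs]
    r1 = hwe_exact_test(pairs, dememorization=10000, batches=10,
                        steps_per_batch=2000, seed=6)
    r2 = hwe_exact_test(pairs2, dememorization=10000, batches=10,
                        steps_per_batch=2000, seed=7)
    assert r1.p_value == pytest.approx(r2.p_value,
                                       abs=3 * (r1.se + r2.se) + 1e-3)


def test_hwe_monomorphic_is_explicit_error():
    with pytest.raises(MonomorphicLocusError):
        hwe_exact_test([("A", "A"), ("A", "A")])


# ---------------------------------------------------------------------------
# Ewens-Watterson


def test_ew_worked_partition_case():
    """2n=4, k=2, observed partition (2,2): null weights are 8/11 on
    (3,1) and 3/11 on (2,2); F_exp = 6.5/11 and p = P(F <= 0.5) = 3/11."""
    res = ew_test([2, 2])
    assert res.method == "exact"
    assert res.f_obs == pytest.approx(0.5)
    assert res.f_exp == pytest.approx(6.5 / 11)
    assert res.p_value == pytest.approx(3 / 11)
    assert res.fnd < 0  # more even than the null mean


def test_ew_all_singletons_boundary():
    """k = 2n: F_obs = 1/(2n) is the minimum; p equals the null mass of
    the all-singleton partition."""
    n_copies = 8
    res = ew_test([1] * n_copies)
    fs, probs = ewens_null_exact(n_copies, n_copies)
    assert len(fs) == 1 and res.p_value == pytest.approx(1.0)
    assert res.f_obs == pytest.approx(1 / n_copies)


def test_ew_monomorphic_is_explicit_error():
    with pytest.raises(MonomorphicLocusError):
        ew_test([10])


@pytest.mark.parametrize("n_copies, k", [(12, 3), (20, 5), (30, 10)])
def test_ewens_exact_null_matches_independent_enumeration(n_copies, k):
    fs, probs = ewens_null_exact(n_copies, k)
    fs2, probs2 = ewens_null_brute(n_copies, k)
    assert probs.sum() == pytest.approx(1.0)
    assert np.allclose(np.sort(fs), np.sort(fs2))
    order1, order2 = np.argsort(fs), np.argsort(fs2)
    assert np.allclose(probs[order1], probs2[order2])


def test_ewens_mc_matches_enumeration():
    """Monte-Carlo F_exp for (2n=40, k=10) agrees with full partition
    enumeration within 3 batch standard errors."""
    fs_exact, probs = ewens_null_exact(40, 10)
    f_exp_exact = float(np.dot(fs_exact, probs))
    sample = _ewens_null_sample(40, 10, n_sim=40000, seed=17)
    batches = sample.reshape(20, -1).mean(axis=1)
    se = batches.std(ddof=1) / np.sqrt(len(batches))
    assert sample.mean() == pytest.approx(f_exp_exact, abs=3 * se)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_step_up_hand_example():
    assert bh_adjust([0.005, 0.01, 0.03, 0.04]) == pytest.approx(
        [0.02, 0.02, 0.04, 0.04])


def test_bh_identities_and_bounds():
    assert bh_adjust([0.2]) == [0.2]
    assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])
    rng = np.random.default_rng(0)
    p = rng.random(50)
    adj = np.array(bh_adjust(list(p)))
    assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
    with pytest.raises(ValueError):
        bh_adjust([-0.1, 0.5])
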