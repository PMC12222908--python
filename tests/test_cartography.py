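"""Haplotype profile matrices and classical MDS embeddings."""

import numpy as np
import pandas as pd
import pytest

from hladiv import HaplotypeFrequencySet, classical_mds, \
    population_distances, profile_matrix


def _hfs(freqs: dict):
    haps = sorted(freqs)
    return HaplotypeFrequencySet(("A", "B"), haps,
                                 np.array([freqs[h] for h in haps]))


def test_profile_matrix_thresholding():
    sets = {
        "P": _hfs({("a1", "b1"): 0.6, ("a2", "b2"): 0.391, ("a3", "b3"): 0.009}),
        "Q": _hfs({("a1", "b1"): 0.97, ("a2", "b2"): 0.009, ("a4", "b4"): 0.021}),
    }
    prof = profile_matrix(sets, threshold=0.01)
    cols = set(prof.values.columns)
    assert "a3~b3" not in cols          # below threshold everywhere
    assert "a4~b4" in cols              # kept: above threshold in one population
    assert prof.values.loc["P", "a4~b4"] == 0.0
    assert prof.values.loc["Q", "a2~b2"] == pytest.approx(0.009)  # kept via P


def test_identical_populations_identical_rows_and_coincident_points():
    f = {("a1", "b1"): 0.7, ("a2", "b2"): 0.3}
    prof = profile_matrix({"P": _hfs(f), "Q": _hfs(f)})
    assert np.allclose(prof.values.loc["P"], prof.values.loc["Q"])
    emb = classical_mds(population_distances(prof))
    assert np.allclose(emb.coordinates[0], emb.coordinates[1], atol=1e-9)


def test_population_distances_metrics():
    prof = profile_matrix({
        "P": _hfs({("a1", "b1"): 1.0}),
        "Q": _hfs({("a2", "b2"): 1.0}),
    })
    d = population_distances(prof, metric="euclidean")
    assert d.loc["P", "Q"] == pytest.approx(np.sqrt(2))
    dh = population_distances(prof, metric="hellinger")
    assert dh.loc["P", "Q"] == pytest.approx(1.0)
    assert np.allclose(np.diag(d), 0)
    with pytest.raises(ValueError):
        population_distances(prof, metric="manhattan")


def test_mds_3_4_5_triangle():
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    emb = classical_mds(D)
    C = emb.coordinates
    re_d = np.linalg.norm(C[:, None, :] - C[None, :, :], axis=-1)
    assert np.allclose(re_d, D, atol=1e-9)


@pytest.mark.parametrize("n_points", [3, 5, 8, 10])
def test_mds_reproduces_planar_configurations(n_points):
    rng = np.random.default_rng(n_points)
    X = rng.normal(size=(n_points, 2)) * 3
    D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    emb = classical_mds(D)
    C = emb.coordinates
    re_d = np.linalg.norm(C[:, None] - C[None, :], axis=-1)
    assert np.allclose(re_d, D, atol=1e-9)
    assert np.allclose(C.mean(axis=0), 0, atol=1e-9)  # centroid at origin
    assert emb.variance_explained == pytest.approx(1.0)


def test_mds_matches_skbio_pcoa():
    """Cross-check the embedding distances against scikit-bio's
    principal coordinate analysis on a non-planar configuration."""
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(77)
    X = rng.normal(size=(6, 4))
    D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    ours = classical_mds(D)
    theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D),
                                         number_of_dimensions=2)
    ref = theirs.samples.to_numpy()
    for j in range(2):
        assert np.allclose(np.abs(ours.coordinates[:, j]), np.abs(ref[:, j]),
                           atol=1e-8)


def test_mds_rejects_bad_input():
    with pytest.raises(ValueError):
        classical_mds(np.array([[0, 1], [2, 0]], dtype=float))  # asymmetric


def test_mds_invariant_to_population_order():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(5, 2))
    D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    labels = [f"p{i}" for i in range(5)]
    emb1 = classical_mds(pd.DataFrame(D, index=labels, columns=labels))
    perm = [3, 1, 4, 0, 2]
    Dp = D[np.ix_(perm, perm)]
    emb2 = classical_mds(pd.DataFrame(
        Dp, index=[labels[i] for i in perm], columns=[labels[i] for i in perm]))
    d1 = {frozenset((a, b)): np.linalg.norm(
        emb1.coordinates[emb1.populations.index(a)]
        - emb1.coordinates[emb1.populations.index(b)])
        for a in labels for b in labels if a != b}
    d2 = {frozenset((a, b)): np.linalg.norm(
        emb2.coordinates[emb2.populations.index(a)]
        - emb2.coordinates[emb2.populations.index(b)])
        for a in labels for b in labels if a != b}
    for key in d1:
        assert d1[key] == pytest.approx(d2[key], abs=1e-9)


def test_two_haplotype_regimes_separate():
    """Populations from two distinct haplotype regimes separate along
    the leading axis (positive silhouette between the groups)."""
    regime1 = {("a1", "b1"): 0.8, ("a2", "b2"): 0.2}
    regime2 = {("a3", "b3"): 0.7, ("a4", "b4"): 0.3}
    rng = np.random.default_rng(0)

    def jitter(f):
        w = np.array(list(f.values())) * rng.gamma(50, 1 / 50, len(f))
        return dict(zip(f, w / w.sum()))

    sets = {f"P{i}": _hfs(jitter(regime1)) for i in range(3)}
    sets.update({f"Q{i}": _hfs(jitter(regime2)) for i in range(3)})
    prof = profile_matrix(sets)
    emb = classical_mds(population_distances(prof))
    x = emb.coordinates[:, 0]
    g1, g2 = x[:3], x[3:]
    assert max(g1.max(), g2.max()) - min(g1.min(), g2.min()) > 0
    # separation: intra-group spread far below inter-group gap
    from sklearn.metrics import silhouette_score
    labels = [0, 0, 0, 1, 1, 1]
    assert silhouette_score(emb.coordinates, labels) > 0
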