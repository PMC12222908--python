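"""Genetic cartography: haplotype-frequency profiles and classical MDS.

Populations are summarised by their haplotype frequency profiles for a
locus combination (haplotypes kept when their relative frequency reaches
1% in at least one population), a pairwise distance matrix is computed
on the profiles (Euclidean by default, Hellinger optionally) and the
populations are embedded in two dimensions by classical (Torgerson)
multidimensional scaling: eigendecomposition of the double-centred
squared-distance matrix, coordinates scaled by the square roots of the
top eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeFrequencySet, haplotype_label

DEFAULT_HF_THRESHOLD = 0.01


@dataclass
class ProfileMatrix:
    """Populations x haplotypes relative-frequency profiles after
    thresholding; a haplotype missing from a population is 0."""

    loci: tuple[str, ...]
    threshold: float
    values: pd.DataFrame  # index: populations, columns: haplotype labels


@dataclass
class Embedding:
    """2-D classical MDS embedding with eigen-diagnostics."""

    populations: list[str]
    coordinates: np.ndarray  # (n, 2), centroid at origin
    eigenvalues: np.ndarray  # all eigenvalues, descending
    variance_explained: float  # share carried by the two retained axes

    def as_frame(self) -> pd.DataFrame:
        pos = self.eigenvalues[self.eigenvalues > 0]
        shares = (self.eigenvalues[:2] / pos.sum()) if pos.sum() > 0 else [0, 0]
        return pd.DataFrame(
            {"population": self.populations,
             "dim1": self.coordinates[:, 0], "dim2": self.coordinates[:, 1],
             "eig1_share": shares[0], "eig2_share": shares[1]}
        )


def profile_matrix(
    hap_sets: dict[str, HaplotypeFrequencySet],
    threshold: float = DEFAULT_HF_THRESHOLD,
) -> ProfileMatrix:
    """Build the thresholded haplotype-frequency profile matrix.

    Keeps every haplotype whose frequency reaches *threshold* in at
    least one population.
    """
    if len(hap_sets) < 2:
        raise ValueError("need haplotype sets for at least two populations")
    loci_set = {hs.loci for hs in hap_sets.values()}
    if len(loci_set) != 1:
        raise ValueError(f"mixed locus combinations: {loci_set}")
    (loci,) = loci_set
    keep = set()
    for hs in hap_sets.values():
        for h, f in hs.as_dict().items():
            if f >= threshold:
                keep.add(h)
    if not keep:
        raise ValueError("no haplotype passes the frequency threshold in any population")
    cols = sorted(keep)
    rows = {}
    for pop, hs in hap_sets.items():
        d = hs.as_dict()
        rows[pop] = [d.get(h, 0.0) for h in cols]
    values = pd.DataFrame.from_dict(
        rows, orient="index", columns=[haplotype_label(h) for h in cols]
    )
    return ProfileMatrix(loci, threshold, values)


def population_distances(profiles: ProfileMatrix, metric: str = "euclidean"
                         ) -> pd.DataFrame:
    """Pairwise distances between population profiles.

    ``euclidean`` (default) acts on the thresholded relative-frequency
    rows; ``hellinger`` uses sqrt-frequency geometry on the same rows.
    """
    X = profiles.values.to_numpy(dtype=float)
    if metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt(np.sum(diff**2, axis=-1))
    elif metric == "hellinger":
        R = np.sqrt(X)
        diff = R[:, None, :] - R[None, :, :]
        D = np.sqrt(np.sum(diff**2, axis=-1)) / np.sqrt(2.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    pops = list(profiles.values.index)
    return pd.DataFrame(D, index=pops, columns=pops)


def classical_mds(distances: pd.DataFrame | np.ndarray, dims: int = 2) -> Embedding:
    """Classical (Torgerson) MDS of a symmetric distance matrix.

    Double-centres the squared distances, takes the top *dims*
    eigenpairs and scales eigenvectors by sqrt(eigenvalue).  Negative
    eigenvalues (non-Euclidean input) are truncated with a warning.  The
    orientation is canonicalised by flipping each axis so the first
    population's coordinate is non-negative.
    """
    if isinstance(distances, pd.DataFrame):
        pops = list(distances.index)
        D = distances.to_numpy(dtype=float)
    else:
        D = np.asarray(distances, dtype=float)
        pops = [f"pop{i}" for i in range(D.shape[0])]
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-8) or np.any(D < -1e-12):
        raise ValueError("distances must be non-negative with zero diagonal")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if np.any(eigvals[:dims] < -1e-9 * max(1.0, abs(eigvals[0]))):
        warnings.warn("negative eigenvalues truncated: distances are not "
                      "exactly Euclidean")
    lam = np.clip(eigvals[:dims], 0.0, None)
    coords = eigvecs[:, :dims] * np.sqrt(lam)
    # canonical orientation: first population non-negative on each axis
    for j in range(coords.shape[1]):
        col = coords[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, j] = -col
    pos = eigvals[eigvals > 0]
    var = float(lam.sum() / pos.sum()) if pos.sum() > 0 else 0.0
    return Embedding(pops, coords, eigvals, var)
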