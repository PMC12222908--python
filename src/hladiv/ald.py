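"""Asymmetric linkage disequilibrium (ALD) between pairs of loci.

For multi-allelic loci the association between loci A and B need not be
symmetric.  ALD measures it directionally through conditional
homozygosity: with haplotype frequencies h_ab and marginals f_a, f_b,

    F(A)   = sum_a f_a^2
    F(A/B) = sum_b sum_a h_ab^2 / f_b
    W_{A/B} = sqrt( (F(A/B) - F(A)) / (1 - F(A)) )

W lies in [0, 1]; it is 0 under independence, 1 when the conditioning
locus determines the focal locus, and the two directions coincide with
|r| when both loci are bi-allelic.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .genotypes import GenotypeTable
from .haplotypes import HaplotypeFrequencySet, em_haplotypes

_MIN_MARGINAL = 1e-12


@dataclass
class ALDResult:
    """Directed ALD for one locus pair; ``w_a_given_b`` conditions the
    first locus on the second."""

    locus_a: str
    locus_b: str
    w_a_given_b: float
    w_b_given_a: float


def _directed_w(haps: dict[tuple[str, str], float], focal: int) -> float:
    cond = 1 - focal
    f_focal: dict[str, float] = {}
    f_cond: dict[str, float] = {}
    for hap, freq in haps.items():
        f_focal[hap[focal]] = f_focal.get(hap[focal], 0.0) + freq
        f_cond[hap[cond]] = f_cond.get(hap[cond], 0.0) + freq
    F_a = sum(p * p for p in f_focal.values())
    if 1.0 - F_a <= _MIN_MARGINAL:
        warnings.warn("monomorphic focal locus: ALD defined as 0")
        return 0.0
    F_cond_sum = 0.0
    for b, fb in f_cond.items():
        if fb < _MIN_MARGINAL:
            continue  # avoid 0/0 on vanishing conditioning alleles
        F_cond_sum += sum(
            freq * freq for hap, freq in haps.items() if hap[cond] == b
        ) / fb
    ratio = (F_cond_sum - F_a) / (1.0 - F_a)
    return math.sqrt(min(max(ratio, 0.0), 1.0))


def ald(haplotypes: HaplotypeFrequencySet) -> ALDResult:
    """Compute both directed ALD values from 2-locus haplotype frequencies."""
    if len(haplotypes.loci) != 2:
        raise ValueError("ALD is defined for exactly 2 loci")
    haps = {h: f for h, f in haplotypes.as_dict().items()}
    a, b = haplotypes.loci
    return ALDResult(
        locus_a=a,
        locus_b=b,
        w_a_given_b=_directed_w(haps, focal=0),
        w_b_given_a=_directed_w(haps, focal=1),
    )


def ald_matrix(
    table: GenotypeTable,
    loci: tuple[str, ...],
    country: str | None = None,
    tribe: str | None = None,
    population_label: str | None = None,
    **em_kwargs,
) -> pd.DataFrame:
    """All pairwise directed ALD values for one population.

    Haplotype frequencies come from 2-locus EM per pair.  Returns a long
    table (population, focal locus, conditioning locus, W) with both
    directions for every pair.
    """
    label = population_label or (tribe or country or "all")
    rows = []
    for la, lb in itertools.combinations(loci, 2):
        fit = em_haplotypes(table, (la, lb), country=country, tribe=tribe, **em_kwargs)
        res = ald(fit)
        rows.append({"population": label, "focal_locus": la,
                     "conditioning_locus": lb, "w": res.w_a_given_b})
        rows.append({"population": label, "focal_locus": lb,
                     "conditioning_locus": la, "w": res.w_b_given_a})
    return pd.DataFrame(rows)
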