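"""Allele frequency estimation by direct counting, binning and summaries.

Each fully typed subject contributes two gene copies at a locus; allele
frequency is count / 2n.  Frequencies are binned as high (>= 5%),
intermediate (1% to < 5%) or low (< 1%), and population-unique alleles
(observed in exactly one population at a locus) are tabulated together
with the frequency mass they carry.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, parse_allele

HIGH_THRESHOLD = 0.05
LOW_THRESHOLD = 0.01


class NoDataError(ValueError):
    """Selection contains no fully typed subject."""


@dataclass
class AlleleFrequencySet:
    """Per-locus, per-population allele counts and relative frequencies.

    ``entries`` has columns ``allele`` (canonical string), ``count``
    (gene copies, int) and ``frequency``; counts sum to 2 * n_subjects
    and frequencies to 1.  Unobserved alleles are absent, not zero.
    """

    locus: str
    population: str
    n_subjects: int
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        total = int(self.entries["count"].sum())
        if total != 2 * self.n_subjects:
            raise ValueError(f"counts sum to {total}, expected {2 * self.n_subjects}")
        if abs(self.entries["frequency"].sum() - 1.0) > 1e-12:
            raise ValueError("frequencies do not sum to 1")

    @property
    def frequencies(self) -> dict[str, float]:
        return dict(zip(self.entries["allele"], self.entries["frequency"]))

    @property
    def counts(self) -> dict[str, int]:
        return dict(zip(self.entries["allele"], self.entries["count"]))

    @property
    def richness(self) -> int:
        return len(self.entries)


def count_alleles(
    table: GenotypeTable,
    locus: str,
    country: str | None = None,
    tribe: str | None = None,
    population_label: str | None = None,
) -> AlleleFrequencySet:
    """Direct-count allele frequencies at *locus* for one population."""
    sub = table.subset(country=country, tribe=tribe)
    rows = sub.typed_at(locus)
    if rows.empty:
        raise NoDataError(f"no fully typed subjects at {locus} for "
                          f"country={country!r} tribe={tribe!r}")
    tally: Counter[str] = Counter()
    for a, b in zip(rows[f"{locus}_1"], rows[f"{locus}_2"]):
        tally[str(parse_allele(a))] += 1
        tally[str(parse_allele(b))] += 1
    n = len(rows)
    alleles = sorted(tally)
    counts = np.array([tally[a] for a in alleles], dtype=int)
    entries = pd.DataFrame(
        {"allele": alleles, "count": counts, "frequency": counts / (2 * n)}
    )
    label = population_label or (tribe or country or "all")
    return AlleleFrequencySet(locus, label, n, entries)


def classify_frequency(freq: float) -> str:
    """Bin a frequency: high (>=5%), low (<1%) or intermediate."""
    if not 0 < freq <= 1:
        raise ValueError(f"frequency out of range (0, 1]: {freq}")
    if freq >= HIGH_THRESHOLD:
        return "high"
    if freq < LOW_THRESHOLD:
        return "low"
    return "intermediate"


def top_alleles(freq_set: AlleleFrequencySet, threshold: float = HIGH_THRESHOLD) -> list[str]:
    """Alleles at or above *threshold*, descending frequency, ties lexicographic."""
    e = freq_set.entries
    hits = e[e["frequency"] >= threshold]
    hits = hits.sort_values(["frequency", "allele"], ascending=[False, True])
    return list(hits["allele"])


def unique_allele_table(freq_sets: dict[str, AlleleFrequencySet]) -> pd.DataFrame:
    """Population-unique alleles at one locus across >= 2 populations.

    An allele is unique to a population iff observed (nonzero count) in
    exactly one.  Returns one row per population with the number of
    unique alleles and the summed relative-frequency percentage those
    alleles carry in that population.
    """
    if len(freq_sets) < 2:
        raise ValueError("need at least two populations")
    loci = {fs.locus for fs in freq_sets.values()}
    if len(loci) != 1:
        raise ValueError(f"mixed loci: {sorted(loci)}")
    seen_in: Counter[str] = Counter()
    for fs in freq_sets.values():
        seen_in.update(fs.frequencies.keys())
    rows = []
    for pop, fs in freq_sets.items():
        uniq = [a for a in fs.frequencies if seen_in[a] == 1]
        mass = sum(fs.frequencies[a] for a in uniq)
        rows.append(
            {"population": pop, "locus": fs.locus, "n_subjects": fs.n_subjects,
             "n_unique_alleles": len(uniq), "unique_frequency_pct": 100.0 * mass}
        )
    return pd.DataFrame(rows)


def frequency_long_table(freq_sets: list[AlleleFrequencySet]) -> pd.DataFrame:
    """Long-format export: population, locus, allele, count, frequency, bin."""
    frames = []
    for fs in freq_sets:
        e = fs.entries.copy()
        e.insert(0, "population", fs.population)
        e.insert(1, "locus", fs.locus)
        e["bin"] = e["frequency"].map(classify_frequency)
        frames.append(e)
    return pd.concat(frames, ignore_index=True)
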