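"""Within-locus allele co-inheritance ("inheritance pattern") tables.

Each subject carries an unordered pair of alleles at a locus; the pair
frequencies summarise how often two alleles are inherited together in a
population and feed alluvial/Sankey-style plots.  With unphased,
unrelated-subject data this observed genotype co-occurrence is the only
computable reading of an inheritance pattern (no pedigree inference).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .genotypes import GenotypeTable


@dataclass
class PairFrequencyTable:
    """Unordered within-locus allele pair counts for one population;
    counts sum to the number of subjects."""

    population: str
    locus: str
    n_subjects: int
    entries: pd.DataFrame  # allele_1 <= allele_2, count, frequency


def pair_frequencies(
    table: GenotypeTable,
    locus: str,
    country: str | None = None,
    tribe: str | None = None,
    population_label: str | None = None,
) -> PairFrequencyTable:
    """Tabulate each subject's unordered allele pair at *locus*."""
    rows = table.subset(country=country, tribe=tribe).typed_at(locus)
    if rows.empty:
        raise ValueError(f"no fully typed subjects at {locus}")
    tally: Counter[tuple[str, str]] = Counter()
    for a, b in zip(rows[f"{locus}_1"], rows[f"{locus}_2"]):
        tally[tuple(sorted((a, b)))] += 1
    n = len(rows)
    entries = pd.DataFrame(
        [{"allele_1": a1, "allele_2": a2, "count": c, "frequency": c / n}
         for (a1, a2), c in sorted(tally.items())]
    )
    label = population_label or (tribe or country or "all")
    return PairFrequencyTable(label, locus, n, entries)


def pair_frequency_long_table(tables: list[PairFrequencyTable]) -> pd.DataFrame:
    """Long-format export across populations for plotting tools."""
    frames = []
    for t in tables:
        e = t.entries.copy()
        e.insert(0, "population", t.population)
        e.insert(1, "locus", t.locus)
        frames.append(e)
    return pd.concat(frames, ignore_index=True)
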