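"""Parsing, validation and cleaning of multi-locus HLA genotype tables.

HLA class I alleles are handled at 2-field ("4-digit") resolution, e.g.
``A*02:01``: the first field is the allele group, the second the specific
protein.  Higher-resolution names (synonymous / non-coding fields) are
truncated; expression suffixes (N, L, S, C, A, Q) and an optional ``HLA-``
prefix are stripped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

LOCI = ("A", "B", "C")

#: default column layout of a genotype CSV/TSV
DEFAULT_SCHEMA: dict[str, str] = {
    "pid": "PID",
    "country": "country",
    "tribe": "tribe",
    **{f"{locus}_{i}": f"{locus}_{i}" for locus in LOCI for i in (1, 2)},
}

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?(?P<locus>[A-Z][A-Z0-9]*)\*"
    r"(?P<fields>\d+(?::\d+)*)"
    r"(?P<suffix>[NLSCAQ]?)$"
)


class AlleleParseError(ValueError):
    """Raised for tokens that are not valid 2-field class I allele names."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """A class I HLA allele at 2-field resolution.

    Ordering is lexicographic on (locus, field1, field2), which matches
    the sort order of the canonical string rendering.
    """

    locus: str
    field1: str
    field2: str

    def __str__(self) -> str:
        return f"{self.locus}*{self.field1}:{self.field2}"


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of alleles at one locus (homozygotes allowed)."""

    locus: str
    alleles: tuple[AlleleName, AlleleName]

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a.locus != self.locus or b.locus != self.locus:
            raise ValueError(f"allele loci {a}, {b} do not match genotype locus {self.locus}")
        if b < a:  # store order-independently
            object.__setattr__(self, "alleles", (b, a))

    @property
    def is_heterozygous(self) -> bool:
        return self.alleles[0] != self.alleles[1]


def parse_allele(text: str, loci: Sequence[str] = LOCI) -> AlleleName:
    """Parse an allele name, truncating to 2-field resolution.

    Accepts an optional ``HLA-`` prefix and a trailing expression suffix
    (e.g. ``N`` for null); both are stripped.  Raises
    :class:`AlleleParseError` for malformed names, names with fewer than
    two fields, or loci outside *loci*.
    """
    token = str(text).strip()
    if not token:
        raise AlleleParseError("empty allele name")
    m = _ALLELE_RE.match(token)
    if m is None:
        raise AlleleParseError(f"malformed allele name: {token!r}")
    locus = m.group("locus")
    if locus not in loci:
        raise AlleleParseError(f"locus {locus!r} not one of {list(loci)} in {token!r}")
    fields = m.group("fields").split(":")
    if len(fields) < 2:
        raise AlleleParseError(f"need 2-field resolution, got {token!r}")
    return AlleleName(locus, fields[0], fields[1])


@dataclass
class GenotypeTable:
    """Subjects x loci table of unordered allele pairs with population labels.

    ``data`` holds one row per subject with columns ``pid``, ``country``,
    ``tribe`` (may be NA) and, per locus, ``<L>_1``/``<L>_2`` canonical
    2-field allele strings (NA where untyped).
    """

    data: pd.DataFrame
    loci: tuple[str, ...] = LOCI

    def __post_init__(self) -> None:
        required = {"pid", "country"} | {f"{l}_{i}" for l in self.loci for i in (1, 2)}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"genotype table missing columns: {sorted(missing)}")
        if "tribe" not in self.data.columns:
            self.data = self.data.assign(tribe=pd.NA)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def countries(self) -> list[str]:
        return sorted(self.data["country"].dropna().unique())

    def subset(self, country: str | None = None, tribe: str | None = None) -> "GenotypeTable":
        d = self.data
        if country is not None:
            d = d[d["country"] == country]
        if tribe is not None:
            d = d[d["tribe"] == tribe]
        return GenotypeTable(d.reset_index(drop=True), self.loci)

    def typed_at(self, locus: str) -> pd.DataFrame:
        """Rows fully typed (both alleles present) at *locus*."""
        c1, c2 = f"{locus}_1", f"{locus}_2"
        d = self.data
        return d[d[c1].notna() & d[c2].notna()]

    def genotypes(self, locus: str) -> list[Genotype]:
        rows = self.typed_at(locus)
        return [
            Genotype(locus, (parse_allele(a), parse_allele(b)))
            for a, b in zip(rows[f"{locus}_1"], rows[f"{locus}_2"])
        ]

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        """Write in the default input layout (round-trips through
        :func:`read_genotype_table` with the default schema)."""
        self.data.rename(columns={"pid": "PID"}).to_csv(path, sep=sep, index=False)


def _canonical_or_na(cell: object, errors: list[str], row_label: object, col: str):
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell is pd.NA:
        return pd.NA
    text = str(cell).strip()
    if text == "" or text.lower() in {"na", "nan", "none", "-"}:
        return pd.NA
    try:
        return str(parse_allele(text))
    except AlleleParseError as exc:
        errors.append(f"row {row_label}, column {col}: {exc}")
        return None  # sentinel: malformed, row rejected


def read_genotype_table(
    source: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
    loci: Sequence[str] = LOCI,
) -> tuple[GenotypeTable, list[str]]:
    """Read a genotype CSV/TSV into a :class:`GenotypeTable`.

    *schema* maps internal names (``pid``, ``country``, ``tribe``,
    ``A_1`` ...) to the file's column headers.  Rows with malformed allele
    cells are dropped and reported (with line numbers) in the returned
    rejection list; more than 50% malformed rows is a hard error.
    """
    path = Path(source)
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if raw.empty:
        raise ValueError(f"empty genotype table: {path}")
    needed = [colmap["pid"], colmap["country"]] + [
        colmap[f"{l}_{i}"] for l in loci for i in (1, 2)
    ]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing mapped columns {missing}")

    rejections: list[str] = []
    rows = []
    for idx, row in raw.iterrows():
        line_no = idx + 2  # header is line 1
        errors: list[str] = []
        rec: dict[str, object] = {
            "pid": row[colmap["pid"]],
            "country": row[colmap["country"]],
            "tribe": row.get(colmap.get("tribe", "tribe"), pd.NA),
        }
        bad = False
        for l in loci:
            for i in (1, 2):
                val = _canonical_or_na(row[colmap[f"{l}_{i}"]], errors, line_no, f"{l}_{i}")
                if val is None:
                    bad = True
                rec[f"{l}_{i}"] = val if val is not None else pd.NA
        if bad:
            rejections.extend(errors)
        else:
            rows.append(rec)
    if len(rejections) and len(rows) < 0.5 * len(raw):
        raise ValueError(
            f"{path}: {len(raw) - len(rows)} of {len(raw)} rows malformed; "
            "refusing to proceed (>50%)"
        )
    table = pd.DataFrame(rows, columns=["pid", "country", "tribe"]
                         + [f"{l}_{i}" for l in loci for i in (1, 2)])
    if table.empty:
        raise ValueError(f"{path}: no parseable rows")
    return GenotypeTable(table, tuple(loci)), rejections


@dataclass
class CleaningReport:
    """Per-subject actions taken during cleaning, exportable as TSV."""

    actions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["pid", "action", "reason"])
    )

    @property
    def n_duplicates_resolved(self) -> int:
        return int((self.actions["action"] == "drop_duplicate").sum())

    def exclusions_per_locus(self, loci: Iterable[str] = LOCI) -> dict[str, int]:
        out = {}
        for locus in loci:
            out[locus] = int(
                self.actions["reason"].str.contains(f"missing allele at {locus}").sum()
            )
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.actions.to_csv(path, sep="\t", index=False)


def clean_genotypes(table: GenotypeTable) -> tuple[GenotypeTable, CleaningReport]:
    """Resolve duplicate subject IDs and flag per-locus missingness.

    Among rows sharing a ``pid`` the row with more non-missing allele
    cells is retained (tie: first occurrence, both logged).  Subjects
    missing an allele at a locus stay in the table but are flagged in the
    report; locus-level analyses use only fully typed subjects at that
    locus (per-locus denominators).  Idempotent.
    """
    allele_cols = [f"{l}_{i}" for l in table.loci for i in (1, 2)]
    d = table.data.reset_index(drop=True)
    completeness = d[allele_cols].notna().sum(axis=1)
    actions = []
    keep_idx = []
    for pid, grp in d.groupby("pid", sort=False):
        if len(grp) == 1:
            keep_idx.append(grp.index[0])
            continue
        best = completeness.loc[grp.index].idxmax()  # first occurrence wins ties
        keep_idx.append(best)
        for i in grp.index:
            if i != best:
                actions.append(
                    {"pid": pid, "action": "drop_duplicate",
                     "reason": f"kept row with {completeness[best]} allele cells "
                               f"over row with {completeness[i]}"}
                )
    keep_idx.sort()
    cleaned = d.loc[keep_idx].reset_index(drop=True)
    for locus in table.loci:
        c1, c2 = f"{locus}_1", f"{locus}_2"
        partial = cleaned[cleaned[c1].isna() | cleaned[c2].isna()]
        for pid in partial["pid"]:
            actions.append(
                {"pid": pid, "action": "exclude_at_locus",
                 "reason": f"missing allele at {locus}"}
            )
    report = CleaningReport(
        pd.DataFrame(actions, columns=["pid", "action", "reason"])
    )
    return GenotypeTable(cleaned, table.loci), report
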