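"""Annual registry tables: data model, CSV I/O, and derived per-year quantities.

A national diagnosis registry, aggregated annually, gives for each calendar
year the number of newly diagnosed patients among children and adolescents
(persons aged 19 or younger), the size of that population, and the number of
19-year-olds.  From these we derive the two quantities the downstream models
consume: the annual incidence rate (per 100 000) and the aging-out proportion
(the fraction of the modelled population that turns 19 and exits each year).

The packaged fixture ``builtin_table()`` is the Slovenian national ADHD
registry series 1997-2013 (hyperkinetic-disorder diagnoses, ICD-10 F90.x,
with Statistical Office population counts).  The final year carries
population data only; operations that need case counts skip or reject it.

CSV schema (version 1): UTF-8, header ``year,new_cases,pop_under19,pop_19``,
one row per year, empty ``new_cases`` meaning not observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "AnnualRegistryRecord",
    "RegistryTable",
    "RegistrySchemaError",
    "RegistryValidationError",
    "UndefinedRateError",
    "load_registry",
    "save_registry",
    "builtin_table",
    "incidence_rate",
    "aging_out_proportion",
    "CSV_COLUMNS",
]

CSV_COLUMNS = ("year", "new_cases", "pop_under19", "pop_19")

PER_100K = 100_000.0


class RegistrySchemaError(ValueError):
    """The input file does not conform to the registry CSV schema."""


class RegistryValidationError(ValueError):
    """The parsed records violate a registry invariant (gap, duplicate, sign)."""


class UndefinedRateError(ValueError):
    """An incidence rate was requested for a year without a case count."""


@dataclass(frozen=True, slots=True)
class AnnualRegistryRecord:
    """One calendar year of registry counts.

    Parameters
    ----------
    year:
        Calendar year.
    new_cases:
        Newly diagnosed patients that year, or ``None`` for years with
        population data only (e.g. a trailing census year).
    pop_under19:
        Number of persons aged 19 or younger.
    pop_19:
        Number of 19-year-olds (the annual outflow cohort).
    """

    year: int
    new_cases: int | None
    pop_under19: int
    pop_19: int

    def __post_init__(self) -> None:
        if self.pop_under19 <= 0:
            raise RegistryValidationError(
                f"year {self.year}: pop_under19 must be positive, got {self.pop_under19}"
            )
        if self.pop_19 < 0:
            raise RegistryValidationError(
                f"year {self.year}: pop_19 must be non-negative, got {self.pop_19}"
            )
        if self.pop_19 > self.pop_under19:
            raise RegistryValidationError(
                f"year {self.year}: pop_19 ({self.pop_19}) exceeds pop_under19 "
                f"({self.pop_under19})"
            )
        if self.new_cases is not None:
            if self.new_cases < 0:
                raise RegistryValidationError(
                    f"year {self.year}: new_cases must be non-negative, got {self.new_cases}"
                )
            if self.new_cases > self.pop_under19:
                raise RegistryValidationError(
                    f"year {self.year}: new_cases ({self.new_cases}) exceeds "
                    f"pop_under19 ({self.pop_under19})"
                )


class RegistryTable:
    """An ordered, gap-free run of :class:`AnnualRegistryRecord`.

    Records are sorted ascending by year on construction; duplicate years and
    gaps in the span raise :class:`RegistryValidationError`.
    """

    def __init__(self, records: Iterable[AnnualRegistryRecord]) -> None:
        recs = sorted(records, key=lambda r: r.year)
        if len(recs) < 2:
            raise RegistryValidationError(
                f"a registry table needs at least 2 records, got {len(recs)}"
            )
        for prev, cur in zip(recs, recs[1:]):
            if cur.year == prev.year:
                raise RegistryValidationError(f"duplicate year {cur.year}")
            if cur.year != prev.year + 1:
                raise RegistryValidationError(
                    f"year gap: missing year {prev.year + 1}"
                )
        self._records: tuple[AnnualRegistryRecord, ...] = tuple(recs)
        self._by_year = {r.year: r for r in recs}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[AnnualRegistryRecord]:
        return iter(self._records)

    def __getitem__(self, year: int) -> AnnualRegistryRecord:
        try:
            return self._by_year[year]
        except KeyError:
            raise KeyError(f"year {year} not in registry span {self.span}") from None

    def __contains__(self, year: int) -> bool:
        return year in self._by_year

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegistryTable):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:
        lo, hi = self.span
        return f"RegistryTable({lo}-{hi}, {len(self)} records)"

    # -- views ---------------------------------------------------------------
    @property
    def records(self) -> tuple[AnnualRegistryRecord, ...]:
        return self._records

    @property
    def span(self) -> tuple[int, int]:
        """(first year, last year) of the table."""
        return self._records[0].year, self._records[-1].year

    @property
    def years(self) -> range:
        lo, hi = self.span
        return range(lo, hi + 1)

    def case_years(self) -> list[int]:
        """Years for which a case count is present."""
        return [r.year for r in self._records if r.new_cases is not None]

    def to_frame(self) -> pd.DataFrame:
        """The table as a DataFrame with the canonical column set."""
        return pd.DataFrame(
            {
                "year": [r.year for r in self._records],
                "new_cases": pd.array(
                    [r.new_cases for r in self._records], dtype="Int64"
                ),
                "pop_under19": [r.pop_under19 for r in self._records],
                "pop_19": [r.pop_19 for r in self._records],
            }
        )


def incidence_rate(record: AnnualRegistryRecord) -> float:
    """Annual incidence rate per 100 000 persons aged <=19.

    Defined as ``100000 * new_cases / pop_under19``.  All downstream fitting
    uses these full-precision ratios, never display-rounded rates.
    """
    if record.new_cases is None:
        raise UndefinedRateError(
            f"year {record.year} has no case count; incidence rate undefined"
        )
    return PER_100K * record.new_cases / record.pop_under19


def aging_out_proportion(record: AnnualRegistryRecord) -> float:
    """Fraction of the <=19 population that is 19 years old (dimensionless).

    This is the annual outflow proportion of the prevalence recursion: the
    share of the modelled population that reaches age 19 and exits.
    """
    return record.pop_19 / record.pop_under19


def load_registry(path: str | Path) -> RegistryTable:
    """Read a registry CSV (schema version 1) into a validated table.

    Raises
    ------
    RegistrySchemaError
        If the file is empty or a required column is missing.
    RegistryValidationError
        On duplicate years, gaps, or negative counts.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"year": "Int64"})
    except pd.errors.EmptyDataError:
        raise RegistrySchemaError(f"{path}: empty file, expected header "
                                  f"{','.join(CSV_COLUMNS)}") from None
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise RegistrySchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        nc = row.new_cases
        records.append(
            AnnualRegistryRecord(
                year=int(row.year),
                new_cases=None if pd.isna(nc) else int(nc),
                pop_under19=int(row.pop_under19),
                pop_19=int(row.pop_19),
            )
        )
    return RegistryTable(records)


def save_registry(table: RegistryTable, path: str | Path) -> None:
    """Write a table back to the version-1 CSV schema (lossless round-trip)."""
    table.to_frame().to_csv(path, index=False)


def builtin_table() -> RegistryTable:
    """The packaged Slovenian ADHD registry series, 1997-2013.

    Seventeen annual rows of F90.x diagnosis counts and population data; the
    2013 row has population counts only (no case count was published).
    """
    ref = resources.files("incprev.data") / "slovenia_adhd_1997_2013.csv"
    with resources.as_file(ref) as p:
        return load_registry(p)
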