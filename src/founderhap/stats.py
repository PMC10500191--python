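"""Penetrance tabulation and Yates-corrected 2x2 proportion tests.

The chi-square statistic with Yates continuity correction is

    chi2 = n * (max(|ad - bc| - n/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d))

and the two-sided p-value is the chi-square(1) upper tail, which has the
closed form p = erfc(sqrt(chi2 / 2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import PhenotypeRecord

__all__ = [
    "CATEGORIES",
    "CohortSummary",
    "TwoByTwo",
    "ProportionTestResult",
    "summarize_cohort",
    "penetrance",
    "category_count",
    "chi2_sf1",
    "yates_proportion_test",
    "compare_cohorts",
]

# "arterial_any" = taad OR arterial_other (any arterial involvement)
CATEGORIES = ("taad", "arterial_other", "cardio_other", "connective", "arterial_any")


@dataclass(frozen=True)
class CohortSummary:
    """Category counts over one carrier cohort (categories may overlap)."""

    n_total: int
    n_male: int
    n_female: int
    n_taad: int
    n_arterial_any: int
    n_cardio_other: int
    n_connective: int
    n_unaffected: int
    age_mean: float | None
    age_range: tuple[float, float] | None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["age_range"] = list(self.age_range) if self.age_range else None
        return d


@dataclass(frozen=True)
class TwoByTwo:
    """Contingency cells; rows = cohorts, columns = affected/unaffected."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ProportionTestResult:
    chi2: float
    df: int
    p: float
    corrected: bool
    degenerate: bool = False  # a zero marginal made the test undefined

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _has(record: PhenotypeRecord, category: str) -> bool:
    if category == "arterial_any":
        return record.taad or record.arterial_other
    if category in ("taad", "arterial_other", "cardio_other", "connective"):
        return getattr(record, category)
    raise ValueError(f"unknown category {category!r}; one of {CATEGORIES}")


def summarize_cohort(records: Sequence[PhenotypeRecord]) -> CohortSummary:
    """Tabulate sex, phenotype-category and unaffected counts, and ages."""
    if not records:
        raise ValueError("empty cohort")
    ages = [r.age for r in records if r.age is not None]
    return CohortSummary(
        n_total=len(records),
        n_male=sum(r.sex == "male" for r in records),
        n_female=sum(r.sex == "female" for r in records),
        n_taad=sum(r.taad for r in records),
        n_arterial_any=sum(_has(r, "arterial_any") for r in records),
        n_cardio_other=sum(r.cardio_other for r in records),
        n_connective=sum(r.connective for r in records),
        n_unaffected=sum(r.unaffected for r in records),
        age_mean=(sum(ages) / len(ages)) if ages else None,
        age_range=(min(ages), max(ages)) if ages else None,
    )


def penetrance(records: Sequence[PhenotypeRecord], category: str) -> tuple[int, int, float]:
    """(k, n, k/n): carriers expressing *category* over all carriers."""
    if not records:
        raise ValueError("empty cohort")
    k = sum(_has(r, category) for r in records)
    n = len(records)
    return k, n, k / n


def category_count(
    cohort: Sequence[PhenotypeRecord] | Mapping[str, int], category: str
) -> tuple[int, int]:
    """(affected, total) from either phenotype records or a counts mapping.

    A counts mapping (e.g. a literature cohort published only as totals)
    must provide ``n`` and a per-category count keyed by the category name.
    """
    if isinstance(cohort, Mapping):
        if category not in cohort:
            raise ValueError(f"counts mapping lacks category {category!r}")
        return int(cohort[category]), int(cohort["n"])
    k, n, _ = penetrance(cohort, category)
    return k, n


def chi2_sf1(chi2: float) -> float:
    """Chi-square(df=1) upper tail via the closed form erfc(sqrt(x/2))."""
    if chi2 < 0:
        raise ValueError("chi2 must be >= 0")
    return math.erfc(math.sqrt(chi2 / 2.0))


def yates_proportion_test(table: TwoByTwo) -> ProportionTestResult:
    """Two-sided 2x2 proportion test with Yates continuity correction.

    The correction term ``|ad - bc| - n/2`` is clamped at zero, so equal
    proportions give exactly chi2 = 0, p = 1. A zero row or column marginal
    returns chi2 = 0, p = 1 flagged degenerate rather than an error.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return ProportionTestResult(0.0, 1, 1.0, corrected=True, degenerate=True)
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    chi2 = n * num * num / denom
    return ProportionTestResult(chi2, 1, chi2_sf1(chi2), corrected=True)


def compare_cohorts(
    cohort_a: Sequence[PhenotypeRecord] | Mapping[str, int],
    cohort_b: Sequence[PhenotypeRecord] | Mapping[str, int],
    category: str,
) -> tuple[TwoByTwo, ProportionTestResult]:
    """Build the affected/unaffected 2x2 for *category* and test it."""
    ka, na = category_count(cohort_a, category)
    kb, nb = category_count(cohort_b, category)
    table = TwoByTwo(ka, na - ka, kb, nb - kb)
    return table, yates_proportion_test(table)
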