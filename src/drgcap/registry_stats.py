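"""Regional CS-rate comparison (2x2 chi-square) and registry concordance.

The chi-square machinery is written out explicitly rather than delegated
to a statistics library: the Pearson statistic is computed from the
margin-derived expected counts and the one-degree-of-freedom upper tail
is obtained from the complementary error function,

    p = erfc(sqrt(X2 / 2)),

which is the exact chi-square(1) survival function.  Yates' continuity
correction (|O - E| reduced by 0.5, floored at zero) is available as a
flag; the uncorrected Pearson test is the default.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

from .registry_io import DeliveryTable, ValidationError

__all__ = [
    "ContingencyTable2x2",
    "ChiSquareResult",
    "ConcordanceResult",
    "chi_square_2x2",
    "regional_cs_comparison",
    "registry_concordance",
]


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts ``[[a, b], [c, d]]``: rows are groups, columns CS / vaginal."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if value < 0 or not float(value).is_integer():
                raise ValidationError(f"cell {name} must be a nonnegative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) sums."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclasses.dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    yates: bool

    def to_report_dict(self) -> dict[str, object]:
        return {
            "statistic": round(self.statistic, 4),
            "df": self.df,
            "p": self.p_value,
            "yates": self.yates,
        }


@dataclasses.dataclass(frozen=True)
class ConcordanceResult:
    """Count ratio between two registries for one delivery mode."""

    npr_count: int
    mbrn_count: int

    @property
    def ratio(self) -> float:
        return self.npr_count / self.mbrn_count

    def to_report_dict(self) -> dict[str, object]:
        return {
            "npr": self.npr_count,
            "mbrn": self.mbrn_count,
            "ratio": round(self.ratio, 4),
        }


def chi_square_tail_1df(statistic: float) -> float:
    """Upper-tail probability of chi-square with one degree of freedom."""
    if statistic < 0:
        raise ValidationError("chi-square statistic must be nonnegative")
    return math.erfc(math.sqrt(statistic / 2.0))


def chi_square_2x2(table: ContingencyTable2x2, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence on a 2x2 table.

    Raises
    ------
    ValidationError
        If any row or column margin is zero (the table is untestable).
    """
    r1, r2, c1, c2 = table.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ValidationError("zero margin: 2x2 table is untestable")
    n = table.n
    observed = (table.a, table.b, table.c, table.d)
    expected = (r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)
    statistic = 0.0
    for obs, exp in zip(observed, expected):
        deviation = abs(obs - exp)
        if yates:
            deviation = max(deviation - 0.5, 0.0)
        statistic += deviation * deviation / exp
    return ChiSquareResult(
        statistic=statistic,
        df=1,
        p_value=chi_square_tail_1df(statistic),
        yates=yates,
    )


def regional_cs_comparison(
    table: DeliveryTable,
    regions: Mapping[str, str],
    yates: bool = False,
) -> tuple[dict[str, float], ChiSquareResult]:
    """Pooled per-region CS rates and the 2x2 chi-square comparing them.

    Exactly two regions are required; the contingency rows follow the
    order in which the regions first appear in the trust list.
    """
    for trust in table.trusts:
        if trust not in regions:
            raise ValidationError(f"trust {trust!r} has no region assignment")
    region_order: list[str] = []
    pooled: dict[str, list[int]] = {}
    for trust in table.trusts:
        region = regions[trust]
        if region not in pooled:
            region_order.append(region)
            pooled[region] = [0, 0]  # [cs, vaginal]
        pooled[region][0] += table.cs_count(trust)
        pooled[region][1] += table.vaginal_count(trust)
    if len(region_order) != 2:
        raise ValidationError(
            f"regional comparison needs exactly two regions, got {region_order}"
        )
    first, second = region_order
    rates = {
        region: pooled[region][0] / (pooled[region][0] + pooled[region][1])
        for region in region_order
    }
    contingency = ContingencyTable2x2(
        a=pooled[first][0], b=pooled[first][1],
        c=pooled[second][0], d=pooled[second][1],
    )
    return rates, chi_square_2x2(contingency, yates=yates)


def registry_concordance(
    npr: tuple[int, int], mbrn: tuple[int, int]
) -> tuple[ConcordanceResult, ConcordanceResult]:
    """NPR/MBRN count ratios for (vaginal, CS) deliveries.

    Both registries record every delivery; a ratio near 1 indicates the
    patient-registry counts are robust.
    """
    npr_vaginal, npr_cs = npr
    mbrn_vaginal, mbrn_cs = mbrn
    if mbrn_vaginal <= 0 or mbrn_cs <= 0:
        raise ValidationError("MBRN counts must be positive for a ratio")
    return (
        ConcordanceResult(npr_count=npr_vaginal, mbrn_count=mbrn_vaginal),
        ConcordanceResult(npr_count=npr_cs, mbrn_count=mbrn_cs),
    )
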