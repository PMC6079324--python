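"""CS rates, the delivery probability tree, and DRG funding arithmetic.

The funding model treats each delivery as a two-stage branching process:
first caesarean section (probability ``P1``) versus vaginal delivery
(``P2 = 1 - P1``); then, conditional on the branch, assignment to one
DRG leaf — 370/371 for the CS branch (``P3``/``P4``), 372, 373, 373O,
374, 375 for the vaginal branch (``P5``–``P9``).  All probabilities are
estimated as pooled empirical shares from a
:class:`~drgcap.registry_io.DeliveryTable`.

Funding is tariff-times-count: each DRG carries a per-case tariff (in
NOK or EUR) and a trust's CS/vaginal funding is the sum over the DRGs
of that group.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Mapping

from .registry_io import (
    CS_DRGS,
    DRG_CODES,
    VAGINAL_DRGS,
    CurrencyConfig,
    DeliveryTable,
    FundingTable,
    ValidationError,
)

__all__ = [
    "ALL",
    "ProbabilityTree",
    "FundingSummary",
    "TariffTable",
    "cs_rate",
    "estimate_probability_tree",
    "compute_funding",
    "funding_means",
    "convert_currency",
]

#: Sentinel for pooled (all-trust) computations.
ALL = "ALL"

_SUM_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class ProbabilityTree:
    """Branch and leaf probabilities of the delivery outcome tree.

    ``p1``/``p2`` split CS versus vaginal; ``p3``/``p4`` split the CS
    branch over DRGs 370/371; ``p5``–``p9`` split the vaginal branch
    over DRGs 372, 373, 373O, 374, 375.
    """

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float
    p7: float
    p8: float
    p9: float

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} = {value} outside [0, 1]")
        for label, total in (
            ("P1+P2", self.p1 + self.p2),
            ("P3+P4", self.p3 + self.p4),
            ("P5+...+P9", self.p5 + self.p6 + self.p7 + self.p8 + self.p9),
        ):
            if abs(total - 1.0) > _SUM_TOL:
                raise ValidationError(f"{label} = {total} does not sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {f"P{i}": getattr(self, f"p{i}") for i in range(1, 10)}

    def leaf_probabilities(self) -> dict[str, float]:
        """Unconditional probability of each DRG leaf, in DRG display order."""
        return {
            "370": self.p1 * self.p3,
            "371": self.p1 * self.p4,
            "372": self.p2 * self.p5,
            "373": self.p2 * self.p6,
            "373O": self.p2 * self.p7,
            "374": self.p2 * self.p8,
            "375": self.p2 * self.p9,
        }

    def to_report_dict(self) -> dict[str, float]:
        return {k: round(v, 4) for k, v in self.as_dict().items()}


@dataclasses.dataclass(frozen=True)
class TariffTable:
    """Per-case tariff for each DRG, in a single currency."""

    tariffs: Mapping[str, float]
    currency: Literal["NOK", "EUR"] = "EUR"

    def __post_init__(self) -> None:
        if self.currency not in ("NOK", "EUR"):
            raise ValidationError(f"unknown currency {self.currency!r}")
        for drg, tariff in self.tariffs.items():
            if drg not in DRG_CODES:
                raise ValidationError(f"unknown DRG code {drg!r}")
            if tariff < 0:
                raise ValidationError(f"negative tariff for DRG {drg}")

    def tariff_eur(self, drg: str, config: CurrencyConfig) -> float:
        value = self.tariffs[drg]
        if self.currency == "NOK":
            return value / config.nok_per_eur
        return value


@dataclasses.dataclass(frozen=True)
class FundingSummary:
    """Per-trust and pooled funding figures, in EUR."""

    per_trust: Mapping[str, tuple[float, float]]  # trust -> (cs, vaginal)
    mean_per_cs: float | None = None
    mean_per_vaginal: float | None = None

    def cs_funding(self, trust: str) -> float:
        return self.per_trust[trust][0]

    def vaginal_funding(self, trust: str) -> float:
        return self.per_trust[trust][1]

    def total(self, trust: str) -> float:
        cs, vaginal = self.per_trust[trust]
        return cs + vaginal

    def grand_total(self) -> float:
        return sum(self.total(t) for t in self.per_trust)

    def total_cs(self) -> float:
        return sum(cs for cs, _ in self.per_trust.values())

    def total_vaginal(self) -> float:
        return sum(v for _, v in self.per_trust.values())

    def to_report_dict(self) -> dict[str, object]:
        out: dict[str, object] = {
            trust: {
                "cs_funding": round(cs),
                "vaginal_funding": round(vaginal),
                "total": round(cs + vaginal),
            }
            for trust, (cs, vaginal) in self.per_trust.items()
        }
        out["Total"] = {
            "cs_funding": round(self.total_cs()),
            "vaginal_funding": round(self.total_vaginal()),
            "total": round(self.grand_total()),
        }
        if self.mean_per_cs is not None:
            out["mean_per_cs"] = round(self.mean_per_cs)
        if self.mean_per_vaginal is not None:
            out["mean_per_vaginal"] = round(self.mean_per_vaginal)
        return out


def cs_rate(table: DeliveryTable, trust: str = ALL) -> float:
    """Caesarean-section share of deliveries for one trust or pooled over all.

    Raises
    ------
    ValidationError
        If the trust (or the pool) has zero deliveries.
    """
    if trust == ALL:
        total, cs = table.pooled_total(), table.pooled_cs()
    else:
        total, cs = table.total(trust), table.cs_count(trust)
    if total == 0:
        raise ValidationError(f"CS rate undefined: zero deliveries for {trust!r}")
    return cs / total

def estimate_probability_tree(table: DeliveryTable) -> ProbabilityTree:
    """Estimate the outcome tree from pooled empirical DRG shares.

    ``P1`` is the pooled CS rate; ``P3``/``P4`` are pooled shares of DRG
    370/371 within the CS branch; ``P5``–``P9`` pooled shares of the
    five vaginal DRGs within the vaginal branch.  Complements are
    normalised so each level sums to one exactly.
    """
    cs = table.pooled_cs()
    vaginal = table.pooled_vaginal()
    total = table.pooled_total()
    if total == 0:
        raise ValidationError("empty table: no deliveries")
    if cs == 0:
        raise ValidationError("CS branch empty: P3/P4 undefined")
    if vaginal == 0:
        raise ValidationError("vaginal branch empty: P5..P9 undefined")
    p1 = cs / total
    p3 = table.pooled_count("370") / cs
    vaginal_shares = [table.pooled_count(d) / vaginal for d in VAGINAL_DRGS]
    # force exact complements so the tree invariants hold to machine precision
    p5, p6, p7, p8 = vaginal_shares[:4]
    p9 = 1.0 - (p5 + p6 + p7 + p8)
    return ProbabilityTree(
        p1=p1, p2=1.0 - p1, p3=p3, p4=1.0 - p3,
        p5=p5, p6=p6, p7=p7, p8=p8, p9=p9,
    )


def compute_funding(
    table: DeliveryTable,
    tariffs: TariffTable,
    currency: CurrencyConfig | None = None,
) -> FundingSummary:
    """Tariff-times-count funding per trust, in EUR.

    NOK tariffs are converted at ``currency.nok_per_eur`` before
    summing.  A missing tariff is only an error for a DRG with a nonzero
    count.
    """
    config = currency or CurrencyConfig()
    per_trust: dict[str, tuple[float, float]] = {}
    for trust in table.trusts:
        sums = {"cs": 0.0, "vaginal": 0.0}
        for group_name, group in (("cs", CS_DRGS), ("vaginal", VAGINAL_DRGS)):
            for drg in group:
                count = table.count(trust, drg)
                if count == 0:
                    continue
                if drg not in tariffs.tariffs:
                    raise ValidationError(
                        f"no tariff for DRG {drg} (needed by trust {trust!r})"
                    )
                sums[group_name] += count * tariffs.tariff_eur(drg, config)
        per_trust[trust] = (sums["cs"], sums["vaginal"])
    return FundingSummary(per_trust=per_trust)


def funding_means(
    funding: FundingTable, table: DeliveryTable
) -> tuple[float, float]:
    """Pooled mean funding per CS and per vaginal birth, in EUR (unrounded)."""
    funding.check_trusts(table)
    cs_count = table.pooled_cs()
    vaginal_count = table.pooled_vaginal()
    if cs_count == 0 or vaginal_count == 0:
        raise ValidationError("mean funding undefined for zero pooled counts")
    total_cs = sum(funding.cs_funding(t) for t in funding.trusts)
    total_vaginal = sum(funding.vaginal_funding(t) for t in funding.trusts)
    return total_cs / cs_count, total_vaginal / vaginal_count


def convert_currency(
    amount: float,
    from_currency: Literal["NOK", "EUR"],
    to_currency: Literal["NOK", "EUR"],
    config: CurrencyConfig | None = None,
) -> float:
    """Convert between NOK and EUR at ``config.nok_per_eur``; same-currency is identity."""
    config = config or CurrencyConfig()
    for name in (from_currency, to_currency):
        if name not in ("NOK", "EUR"):
            raise ValidationError(f"unknown currency {name!r}")
    if from_currency == to_currency:
        return amount
    if from_currency == "NOK":
        return amount / config.nok_per_eur
    return amount * config.nok_per_eur
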