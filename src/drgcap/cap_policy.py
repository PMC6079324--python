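"""The 15 %-cap counterfactual: fund every trust at a fixed target CS rate.

The policy pays each hospital trust *as if* its caesarean-section rate
were exactly the target rate ``r`` (the WHO-recommended 15 % by
default), keeping the trust's own per-case mean tariffs and total
delivery volume fixed:

    capped_cs(t)      = actual_cs(t)      * r       * N(t) / n_cs(t)
    capped_vaginal(t) = actual_vaginal(t) * (1 - r) * N(t) / n_vag(t)

where ``N(t)`` is the trust's total deliveries.  This is *target-rate
normalisation*: trusts below the target gain, trusts above lose, so the
policy is symmetric around ``r``.  A one-sided variant that only scales
down trusts above the target is available for sensitivity analysis.

The per-trust *difference* is actual minus capped total; positive means
a budget reduction for the trust.  The sum over trusts is the
*released resources* retained by the regional health authority.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import pandas as pd

from .registry_io import DeliveryTable, FundingTable, ValidationError

__all__ = [
    "CapScenarioResult",
    "capped_funding",
    "aggregate_regions",
    "released_resources",
]


@dataclasses.dataclass(frozen=True)
class CapScenarioResult:
    """Counterfactual funding and budget differences under a CS-rate cap."""

    cap_rate: float
    trusts: tuple[str, ...]
    actual_cs: Mapping[str, float]
    actual_vaginal: Mapping[str, float]
    capped_cs: Mapping[str, float]
    capped_vaginal: Mapping[str, float]
    one_sided: bool = False

    def difference(self, trust: str) -> float:
        """Actual minus capped total funding; positive = reduction for the trust."""
        return (
            self.actual_cs[trust]
            + self.actual_vaginal[trust]
            - self.capped_cs[trust]
            - self.capped_vaginal[trust]
        )

    def total_difference(self) -> float:
        return sum(self.difference(t) for t in self.trusts)

    def to_report_frame(self) -> pd.DataFrame:
        rows = []
        for trust in self.trusts:
            rows.append(
                {
                    "trust": trust,
                    "actual_cs": round(self.actual_cs[trust]),
                    "actual_vaginal": round(self.actual_vaginal[trust]),
                    "capped_cs": round(self.capped_cs[trust]),
                    "capped_vaginal": round(self.capped_vaginal[trust]),
                    "difference": round(self.difference(trust)),
                }
            )
        rows.append(
            {
                "trust": "Total",
                "actual_cs": round(sum(self.actual_cs.values())),
                "actual_vaginal": round(sum(self.actual_vaginal.values())),
                "capped_cs": round(sum(self.capped_cs.values())),
                "capped_vaginal": round(sum(self.capped_vaginal.values())),
                "difference": round(self.total_difference()),
            }
        )
        return pd.DataFrame(rows)

    def to_report_dict(self) -> dict[str, object]:
        frame = self.to_report_frame()
        return {row["trust"]: {k: v for k, v in row.items() if k != "trust"}
                for row in frame.to_dict("records")}


def capped_funding(
    funding: FundingTable,
    table: DeliveryTable,
    cap_rate: float = 0.15,
    one_sided: bool = False,
) -> CapScenarioResult:
    """Apply target-rate normalisation at ``cap_rate`` to every trust.

    With ``one_sided=True`` only trusts whose actual CS rate exceeds the
    cap are rescaled; the rest keep their actual funding.

    Raises
    ------
    ValidationError
        If ``cap_rate`` is outside (0, 1) or a trust has zero CS or zero
        vaginal deliveries (the scaling is then undefined).
    """
    if not 0.0 < cap_rate < 1.0:
        raise ValidationError(f"cap_rate must lie in (0, 1), got {cap_rate}")
    funding.check_trusts(table)
    actual_cs: dict[str, float] = {}
    actual_vaginal: dict[str, float] = {}
    capped_cs: dict[str, float] = {}
    capped_vaginal: dict[str, float] = {}
    for trust in table.trusts:
        n_cs = table.cs_count(trust)
        n_vaginal = table.vaginal_count(trust)
        if n_cs == 0 or n_vaginal == 0:
            raise ValidationError(
                f"trust {trust!r} has an empty CS or vaginal group; "
                "capped funding is undefined"
            )
        total = table.total(trust)
        cs_f = funding.cs_funding(trust)
        vag_f = funding.vaginal_funding(trust)
        actual_cs[trust] = cs_f
        actual_vaginal[trust] = vag_f
        if one_sided and n_cs / total <= cap_rate:
            capped_cs[trust] = cs_f
            capped_vaginal[trust] = vag_f
        else:
            capped_cs[trust] = cs_f * (cap_rate * total / n_cs)
            capped_vaginal[trust] = vag_f * ((1.0 - cap_rate) * total / n_vaginal)
    return CapScenarioResult(
        cap_rate=cap_rate,
        trusts=tuple(table.trusts),
        actual_cs=actual_cs,
        actual_vaginal=actual_vaginal,
        capped_cs=capped_cs,
        capped_vaginal=capped_vaginal,
        one_sided=one_sided,
    )


def aggregate_regions(
    result: CapScenarioResult,
    regions: Mapping[str, str],
    funding: FundingTable,
) -> dict[str, dict[str, float]]:
    """Net budget difference and relative impact per region.

    Returns ``{region: {"net_difference": EUR, "relative_impact_pct": %}}``.
    ``net_difference`` keeps the scenario's sign convention (positive =
    reduction); ``relative_impact_pct`` is the signed percentage change
    of the region's delivery budget, so a *gain* prints as a positive
    percentage increase.
    """
    for trust in result.trusts:
        if trust not in regions:
            raise ValidationError(f"trust {trust!r} has no region assignment")
    out: dict[str, dict[str, float]] = {}
    for trust in result.trusts:
        region = regions[trust]
        entry = out.setdefault(region, {"net_difference": 0.0, "_actual": 0.0})
        entry["net_difference"] += result.difference(trust)
        entry["_actual"] += funding.total(trust)
    for region, entry in out.items():
        actual = entry.pop("_actual")
        # budget change of the region: -difference / actual budget
        entry["relative_impact_pct"] = (
            -entry["net_difference"] / actual * 100.0 if actual else 0.0
        )
    return out


def released_resources(result: CapScenarioResult) -> float:
    """Total funding withheld from the trusts under the counterfactual.

    Negative if the region as a whole sits below the cap rate.
    """
    return result.total_difference()
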