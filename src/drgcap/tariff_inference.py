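"""Back out implied per-DRG tariffs from counts and funding totals.

The national per-DRG unit prices behind the funding figures are not part
of the input data, but the linear relation

    funding(trust) = sum_d count(trust, d) * tariff(d)

can be inverted in the least-squares sense, one delivery group at a
time.  For the CS group (two DRGs, four trusts) the system is typically
over-determined and full rank; for the vaginal group (five DRGs, four
trusts) it is under-determined, and the minimum-norm solution is
returned with every non-identifiable DRG flagged, so the caller is never
handed a silently arbitrary pseudo-tariff.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from .registry_io import (
    CS_DRGS,
    VAGINAL_DRGS,
    DeliveryTable,
    FundingTable,
    ValidationError,
)

__all__ = ["TariffEstimate", "infer_tariffs", "implied_mean_tariffs"]


@dataclasses.dataclass(frozen=True)
class TariffEstimate:
    """Least-squares tariff estimates for one delivery group, in EUR per case."""

    group: str
    estimates: dict[str, float]
    residuals: dict[str, float]  # trust -> funding - fitted, EUR
    design_rank: int
    identifiable: dict[str, bool]
    solution_norm_note: str

    def fitted(self, table: DeliveryTable) -> dict[str, float]:
        """Fitted funding per trust implied by the estimates."""
        return {
            trust: sum(
                table.count(trust, drg) * tariff
                for drg, tariff in self.estimates.items()
            )
            for trust in table.trusts
        }

    def to_report_dict(self) -> dict[str, object]:
        return {
            "group": self.group,
            "estimates": {d: round(v, 2) for d, v in self.estimates.items()},
            "identifiable": dict(self.identifiable),
            "design_rank": self.design_rank,
            "residuals": {t: round(v, 2) for t, v in self.residuals.items()},
            "note": self.solution_norm_note,
        }


def infer_tariffs(
    table: DeliveryTable,
    funding: FundingTable,
    group: Literal["CS", "VAGINAL"],
) -> TariffEstimate:
    """Least-squares per-DRG tariffs for one funding group.

    Solves ``counts @ tariffs ~ funding`` over the trusts.  Rank-deficient
    systems yield the minimum-norm solution; a DRG is flagged
    non-identifiable when its design column lies in the span of the
    others (equivalently, when dropping it does not reduce the design
    rank).

    Raises
    ------
    ValidationError
        If the design matrix is all zero (no information about any tariff).
    """
    funding.check_trusts(table)
    if group == "CS":
        drgs = list(CS_DRGS)
        target = np.array([funding.cs_funding(t) for t in table.trusts], dtype=float)
    elif group == "VAGINAL":
        drgs = list(VAGINAL_DRGS)
        target = np.array(
            [funding.vaginal_funding(t) for t in table.trusts], dtype=float
        )
    else:
        raise ValidationError(f"group must be 'CS' or 'VAGINAL', got {group!r}")

    design = np.array(
        [[table.count(t, d) for d in drgs] for t in table.trusts], dtype=float
    )
    if not design.any():
        raise ValidationError(f"all-zero design matrix for group {group}")

    solution, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    fitted = design @ solution
    residuals = dict(zip(table.trusts, (target - fitted).tolist()))

    identifiable: dict[str, bool] = {}
    for j, drg in enumerate(drgs):
        reduced = np.delete(design, j, axis=1)
        # column j adds information iff removing it drops the rank
        identifiable[drg] = bool(np.linalg.matrix_rank(reduced) < rank)

    if rank < len(drgs):
        note = (
            f"rank {rank} < {len(drgs)} unknowns: minimum-norm solution; "
            "flagged DRGs are not individually identifiable"
        )
    else:
        note = "full-rank design: unique least-squares solution"

    return TariffEstimate(
        group=group,
        estimates=dict(zip(drgs, solution.tolist())),
        residuals=residuals,
        design_rank=int(rank),
        identifiable=identifiable,
        solution_norm_note=note,
    )


def implied_mean_tariffs(
    table: DeliveryTable, funding: FundingTable
) -> dict[str, tuple[float, float]]:
    """Per-trust mean funding per CS and per vaginal birth, in EUR.

    Raises
    ------
    ValidationError
        If a trust has zero CS or zero vaginal deliveries.
    """
    funding.check_trusts(table)
    out: dict[str, tuple[float, float]] = {}
    for trust in table.trusts:
        n_cs = table.cs_count(trust)
        n_vaginal = table.vaginal_count(trust)
        if n_cs == 0 or n_vaginal == 0:
            raise ValidationError(f"zero CS or vaginal count for trust {trust!r}")
        out[trust] = (
            funding.cs_funding(trust) / n_cs,
            funding.vaginal_funding(trust) / n_vaginal,
        )
    return out
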