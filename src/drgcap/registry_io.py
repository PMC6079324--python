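"""Tabular input/output for the delivery-funding pipeline.

The package analyses activity-based funding of deliveries in the four
hospital trusts of Northern Norway (Helgeland, Nordland, University
Hospital of North Norway, Finnmark).  Its two primary inputs are

* a *delivery table*: the number of 2016 deliveries per trust in each of
  the seven obstetric diagnosis-related groups (DRGs) reported to the
  Norwegian Patient Registry (NPR), and
* a *funding table*: the actual DRG funding per trust, in euro, split
  into a caesarean-section (CS) part and a vaginal-birth part.

Both tables are shipped as versioned CSV fixtures (``drgcap.data``) and
can equally be read from user-supplied files with the same layout.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "DRG_CODES",
    "CS_DRGS",
    "VAGINAL_DRGS",
    "DRG_LABELS",
    "DeliveryTable",
    "FundingTable",
    "CurrencyConfig",
    "ValidationError",
    "FormatError",
    "read_delivery_table",
    "read_funding_table",
    "read_region_map",
    "write_report",
    "fixture_path",
]

#: The seven obstetric DRG codes, in display order.  "373O" (outpatient
#: delivery) is a literal string with the letter O, as printed in the
#: national casemix tables.
DRG_CODES: tuple[str, ...] = ("370", "371", "372", "373", "373O", "374", "375")

#: DRGs reimbursed as caesarean sections.
CS_DRGS: tuple[str, ...] = ("370", "371")

#: DRGs reimbursed as vaginal deliveries.  374 (evacuation) and 375
#: (other delivery-related surgery) are grouped with vaginal births, as
#: in the national reporting.
VAGINAL_DRGS: tuple[str, ...] = ("372", "373", "373O", "374", "375")

DRG_LABELS: Mapping[str, str] = {
    "370": "Caesarean section, complication",
    "371": "Caesarean section, no complication",
    "372": "Vaginal birth, complication",
    "373": "Vaginal birth, no complication",
    "373O": "Vaginal birth, outpatient",
    "374": "Evacuation",
    "375": "Other surgery",
}


class ValidationError(ValueError):
    """A table violates a structural invariant (negative count, duplicate trust, ...)."""


class FormatError(ValueError):
    """A file does not have the expected columns or cell types."""


@dataclasses.dataclass(frozen=True)
class DeliveryTable:
    """Delivery counts per trust per DRG.

    Parameters
    ----------
    trusts
        Trust identifiers in display order.
    counts
        Mapping ``(trust, drg_code) -> nonnegative int``.
    """

    trusts: tuple[str, ...]
    counts: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        if not self.trusts:
            raise ValidationError("delivery table needs at least one trust")
        if len(set(self.trusts)) != len(self.trusts):
            raise ValidationError("duplicate trust identifiers")
        for trust in self.trusts:
            for drg in DRG_CODES:
                value = self.counts.get((trust, drg))
                if value is None:
                    raise ValidationError(f"missing count for trust {trust!r}, DRG {drg}")
                if not float(value).is_integer() or value < 0:
                    raise ValidationError(
                        f"count for trust {trust!r}, DRG {drg} must be a nonnegative "
                        f"integer, got {value!r}"
                    )

    def count(self, trust: str, drg: str) -> int:
        return int(self.counts[(trust, drg)])

    def total(self, trust: str) -> int:
        return sum(self.count(trust, d) for d in DRG_CODES)

    def cs_count(self, trust: str) -> int:
        return sum(self.count(trust, d) for d in CS_DRGS)

    def vaginal_count(self, trust: str) -> int:
        return self.total(trust) - self.cs_count(trust)

    def pooled_count(self, drg: str) -> int:
        return sum(self.count(t, drg) for t in self.trusts)

    def pooled_total(self) -> int:
        return sum(self.total(t) for t in self.trusts)

    def pooled_cs(self) -> int:
        return sum(self.cs_count(t) for t in self.trusts)

    def pooled_vaginal(self) -> int:
        return sum(self.vaginal_count(t) for t in self.trusts)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "trust": list(self.trusts),
            **{
                f"drg{d}": [self.count(t, d) for t in self.trusts]
                for d in DRG_CODES
            },
        }
        return pd.DataFrame(data)


@dataclasses.dataclass(frozen=True)
class FundingTable:
    """Actual DRG funding per trust in euro, split CS / vaginal."""

    funding: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for trust, (cs, vaginal) in self.funding.items():
            if cs < 0 or vaginal < 0:
                raise ValidationError(f"negative funding for trust {trust!r}")

    @property
    def trusts(self) -> tuple[str, ...]:
        return tuple(self.funding)

    def cs_funding(self, trust: str) -> float:
        return self.funding[trust][0]

    def vaginal_funding(self, trust: str) -> float:
        return self.funding[trust][1]

    def total(self, trust: str) -> float:
        cs, vaginal = self.funding[trust]
        return cs + vaginal

    def grand_total(self) -> float:
        return sum(self.total(t) for t in self.trusts)

    def check_trusts(self, table: DeliveryTable) -> None:
        """Raise unless this table covers exactly the trusts of ``table``."""
        if set(self.trusts) != set(table.trusts):
            raise ValidationError(
                f"trust sets differ: funding {sorted(self.trusts)} vs "
                f"deliveries {sorted(table.trusts)}"
            )


@dataclasses.dataclass(frozen=True)
class CurrencyConfig:
    """NOK/EUR exchange rate; the 2017-05-16 Norges Bank reference rate by default."""

    nok_per_eur: float = 9.3325

    def __post_init__(self) -> None:
        if not self.nok_per_eur > 0:
            raise ValidationError(f"nok_per_eur must be positive, got {self.nok_per_eur}")


def fixture_path(name: str) -> Path:
    """Path to a shipped CSV fixture (``table1.csv``, ``table2.csv``, ``regions.csv``)."""
    return Path(str(resources.files("drgcap").joinpath("data", name)))


def read_delivery_table(path: str | Path) -> DeliveryTable:
    """Read a delivery-count CSV (columns ``trust,drg370,...,drg375``)."""
    frame = pd.read_csv(path)
    expected = ["trust"] + [f"drg{d}" for d in DRG_CODES]
    for column in expected:
        if column not in frame.columns:
            raise FormatError(f"missing column {column!r} in {path}")
    trusts = [str(t) for t in frame["trust"]]
    counts: dict[tuple[str, str], int] = {}
    for row_index, row in frame.iterrows():
        for drg in DRG_CODES:
            raw = row[f"drg{drg}"]
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric count at row {row_index}, column drg{drg}: {raw!r}"
                ) from None
            if not value.is_integer() or value < 0:
                raise ValidationError(
                    f"count at row {row_index}, column drg{drg} must be a "
                    f"nonnegative integer, got {raw!r}"
                )
            counts[(str(row["trust"]), drg)] = int(value)
    return DeliveryTable(trusts=tuple(trusts), counts=counts)


def read_funding_table(path: str | Path) -> FundingTable:
    """Read an actual-funding CSV (columns ``trust,cs_funding,vaginal_funding``), EUR."""
    frame = pd.read_csv(path)
    for column in ("trust", "cs_funding", "vaginal_funding"):
        if column not in frame.columns:
            raise FormatError(f"missing column {column!r} in {path}")
    funding: dict[str, tuple[float, float]] = {}
    for row_index, row in frame.iterrows():
        try:
            cs = float(row["cs_funding"])
            vaginal = float(row["vaginal_funding"])
        except (TypeError, ValueError):
            raise FormatError(f"non-numeric funding cell at row {row_index}") from None
        trust = str(row["trust"])
        if trust in funding:
            raise ValidationError(f"duplicate trust {trust!r}")
        funding[trust] = (cs, vaginal)
    return FundingTable(funding=funding)


def read_region_map(path: str | Path) -> dict[str, str]:
    """Read a trust-to-region CSV (columns ``trust,region``)."""
    frame = pd.read_csv(path)
    for column in ("trust", "region"):
        if column not in frame.columns:
            raise FormatError(f"missing column {column!r} in {path}")
    regions: dict[str, str] = {}
    for _, row in frame.iterrows():
        trust = str(row["trust"])
        if trust in regions:
            raise ValidationError(f"duplicate trust {trust!r} in region map")
        regions[trust] = str(row["region"])
    return regions


def write_report(result: object, path: str | Path, format: str = "json") -> None:
    """Write a pipeline result to CSV or JSON.

    Money is rounded to whole euro and probabilities/ratios to four
    decimals on output; any object exposing ``to_report_dict()`` (for
    JSON) or ``to_report_frame()`` (for CSV) is accepted.
    """
    path = Path(path)
    if format == "json":
        if hasattr(result, "to_report_dict"):
            payload = result.to_report_dict()
        elif isinstance(result, Mapping):
            payload = dict(result)
        else:
            payload = dataclasses.asdict(result)  # type: ignore[arg-type]
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    elif format == "csv":
        if hasattr(result, "to_report_frame"):
            frame = result.to_report_frame()
        elif isinstance(result, pd.DataFrame):
            frame = result
        else:
            raise TypeError(f"cannot serialise {type(result).__name__} to CSV")
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")
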