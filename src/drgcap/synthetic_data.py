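"""Synthetic delivery tables and Monte-Carlo policy experiments.

Each trust's annual deliveries are modelled as a single multinomial
draw over the seven DRG leaves, with leaf probabilities obtained from a
:class:`~drgcap.funding_model.ProbabilityTree`
(``P1*P3, P1*P4, P2*P5, ..., P2*P9``).  Per-trust totals are fixed —
conditioned on the observed annual volume — rather than Poisson, which
mirrors how the registry reports one year of activity.

``monte_carlo_policy`` propagates this sampling noise through the full
funding + cap pipeline and summarises the distribution of released
resources.  Replicates in which any trust ends up with an empty CS or
vaginal branch (where the cap scaling is undefined) are rejected and
redrawn, and the rejection count is reported.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cap_policy import capped_funding, released_resources
from .funding_model import ProbabilityTree, TariffTable, compute_funding
from .registry_io import (
    DRG_CODES,
    CurrencyConfig,
    DeliveryTable,
    FundingTable,
    ValidationError,
)

__all__ = ["SimulationConfig", "McPolicyResult", "generate_delivery_table", "monte_carlo_policy"]

_MAX_REJECTION_RATE = 0.5


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Inputs of one simulation study.

    ``n_per_trust`` fixes each synthetic trust's annual delivery volume;
    trusts are named ``T1, T2, ...`` unless ``trust_names`` is given.
    """

    n_per_trust: tuple[int, ...]
    tree: ProbabilityTree
    tariffs: TariffTable | None = None
    cap_rate: float = 0.15
    replicates: int = 1
    seed: int = 0
    trust_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if not self.n_per_trust or any(n <= 0 for n in self.n_per_trust):
            raise ValidationError("all per-trust totals must be positive")
        if self.trust_names is not None and len(self.trust_names) != len(self.n_per_trust):
            raise ValidationError("trust_names length must match n_per_trust")

    @property
    def trusts(self) -> tuple[str, ...]:
        if self.trust_names is not None:
            return self.trust_names
        return tuple(f"T{i + 1}" for i in range(len(self.n_per_trust)))


@dataclasses.dataclass(frozen=True)
class McPolicyResult:
    """Distribution of released resources over Monte-Carlo replicates."""

    released: np.ndarray  # EUR, one entry per replicate
    per_trust_differences: dict[str, np.ndarray]
    rejections: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.released))

    @property
    def std(self) -> float:
        return float(np.std(self.released, ddof=1)) if len(self.released) > 1 else 0.0

    def percentiles(self, q=(2.5, 97.5)) -> tuple[float, ...]:
        return tuple(float(v) for v in np.percentile(self.released, q))

    def to_report_dict(self) -> dict[str, object]:
        lo, hi = self.percentiles()
        return {
            "replicates": len(self.released),
            "rejections": self.rejections,
            "released_mean": round(self.mean),
            "released_std": round(self.std),
            "released_p2.5": round(lo),
            "released_p97.5": round(hi),
        }


def _draw_table(config: SimulationConfig, rng: np.random.Generator) -> DeliveryTable:
    leaf_probs = np.array(list(config.tree.leaf_probabilities().values()))
    leaf_probs = leaf_probs / leaf_probs.sum()  # guard rounding at 1e-16 scale
    counts: dict[tuple[str, str], int] = {}
    for trust, n in zip(config.trusts, config.n_per_trust):
        draw = rng.multinomial(n, leaf_probs)
        for drg, value in zip(DRG_CODES, draw):
            counts[(trust, drg)] = int(value)
    return DeliveryTable(trusts=config.trusts, counts=counts)


def generate_delivery_table(config: SimulationConfig) -> DeliveryTable:
    """One synthetic delivery table: a multinomial draw per trust.

    Counts sum exactly to the configured totals; the same seed yields
    the same table.
    """
    rng = np.random.default_rng(config.seed)
    return _draw_table(config, rng)


def monte_carlo_policy(config: SimulationConfig) -> McPolicyResult:
    """Monte-Carlo distribution of the cap policy's released resources.

    Each replicate draws a delivery table, computes tariff-based funding
    and the capped counterfactual, and records the total and per-trust
    budget differences.  Degenerate replicates (an empty CS or vaginal
    branch in any trust) are rejected and redrawn.

    Raises
    ------
    ValidationError
        If ``tariffs`` is missing or the rejection rate exceeds 50 %
        (the cap model is then undefined for volumes this small).
    """
    if config.tariffs is None:
        raise ValidationError("monte_carlo_policy requires a tariff table")
    if not 0.0 < config.cap_rate < 1.0:
        raise ValidationError(f"cap_rate must lie in (0, 1), got {config.cap_rate}")
    rng = np.random.default_rng(config.seed)
    currency = CurrencyConfig()
    released = np.empty(config.replicates)
    per_trust: dict[str, list[float]] = {t: [] for t in config.trusts}
    rejections = 0
    accepted = 0
    while accepted < config.replicates:
        table = _draw_table(config, rng)
        if any(
            table.cs_count(t) == 0 or table.vaginal_count(t) == 0
            for t in table.trusts
        ):
            rejections += 1
            attempts = rejections + accepted
            if attempts >= 20 and rejections / attempts > _MAX_REJECTION_RATE:
                raise ValidationError(
                    "rejection rate above 50%: cap model undefined at this volume"
                )
            continue
        summary = compute_funding(table, config.tariffs, currency)
        funding = FundingTable(funding={t: summary.per_trust[t] for t in table.trusts})
        result = capped_funding(funding, table, config.cap_rate)
        released[accepted] = released_resources(result)
        for trust in config.trusts:
            per_trust[trust].append(result.difference(trust))
        accepted += 1
    return McPolicyResult(
        released=released,
        per_trust_differences={t: np.array(v) for t, v in per_trust.items()},
        rejections=rejections,
    )
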