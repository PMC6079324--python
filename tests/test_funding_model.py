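"""CS rates, probability-tree estimation, funding arithmetic, currency."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drgcap import (
    ALL,
    CurrencyConfig,
    DeliveryTable,
    ProbabilityTree,
    TariffTable,
    ValidationError,
    compute_funding,
    convert_currency,
    cs_rate,
    estimate_probability_tree,
    funding_means,
)
from drgcap.registry_io import DRG_CODES


def _table(trust_counts):
    trusts = tuple(trust_counts)
    counts = {
        (t, d): trust_counts[t].get(d, 0) for t in trusts for d in DRG_CODES
    }
    return DeliveryTable(trusts=trusts, counts=counts)


count_row = st.fixed_dictionaries({d: st.integers(0, 500) for d in DRG_CODES})


class TestCsRate:
    def test_pooled_rate_matches_2016_registry(self, table1):
        assert cs_rate(table1, ALL) == pytest.approx(850 / 4860)
        assert round(100 * cs_rate(table1, ALL), 1) == 17.5

    @pytest.mark.parametrize(
        "trust, expected",
        [("Helgeland", 88 / 633), ("Nordland", 215 / 1402),
         ("University", 428 / 2115), ("Finnmark", 119 / 710)],
    )
    def test_per_trust_rates(self, table1, trust, expected):
        assert cs_rate(table1, trust) == pytest.approx(expected)

    def test_all_cs_table_rate_is_one(self):
        assert cs_rate(_table({"T": {"370": 3, "371": 2}})) == 1.0

    def test_zero_deliveries_raise(self):
        with pytest.raises(ValidationError, match="zero deliveries"):
            cs_rate(_table({"T": {}}))

    @given(rows=st.lists(count_row, min_size=1, max_size=5))
    @settings(deadline=None)
    def test_pooled_rate_is_count_weighted_mean(self, rows):
        trust_counts = {f"T{i}": row for i, row in enumerate(rows)}
        table = _table(trust_counts)
        if table.pooled_total() == 0:
            return
        weighted = sum(
            table.total(t) * cs_rate(table, t)
            for t in table.trusts
            if table.total(t) > 0
        ) / table.pooled_total()
        assert cs_rate(table, ALL) == pytest.approx(weighted, rel=1e-12)


class TestProbabilityTree:
    def test_branch_probabilities_from_fixture(self, table1):
        tree = estimate_probability_tree(table1)
        assert tree.p1 == pytest.approx(850 / 4860)
        assert round(tree.p1, 3) == 0.175
        assert round(tree.p2, 3) == 0.825
        assert tree.p3 == pytest.approx(460 / 850)  # DRG 370 share of CS
        assert tree.p6 == pytest.approx(2701 / 4010)  # DRG 373 share of vaginal

    def test_leaf_probabilities_sum_to_one(self, table1):
        tree = estimate_probability_tree(table1)
        assert sum(tree.leaf_probabilities().values()) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_one_branch_tree(self):
        table = _table({"T": {"373": 9, "371": 1}})
        tree = estimate_probability_tree(table)
        assert tree.p1 == pytest.approx(1 / 10)
        assert tree.p4 == 1.0
        assert tree.p6 == 1.0

    def test_empty_branch_named_in_error(self):
        with pytest.raises(ValidationError, match="CS branch"):
            estimate_probability_tree(_table({"T": {"373": 5}}))
        with pytest.raises(ValidationError, match="vaginal branch"):
            estimate_probability_tree(_table({"T": {"370": 5}}))

    @given(rows=st.lists(count_row, min_size=1, max_size=4))
    @settings(deadline=None)
    def test_sum_to_one_invariants(self, rows):
        table = _table({f"T{i}": row for i, row in enumerate(rows)})
        if table.pooled_cs() == 0 or table.pooled_vaginal() == 0:
            return
        tree = estimate_probability_tree(table)
        assert tree.p1 + tree.p2 == pytest.approx(1.0, abs=1e-12)
        assert tree.p3 + tree.p4 == pytest.approx(1.0, abs=1e-12)
        assert tree.p5 + tree.p6 + tree.p7 + tree.p8 + tree.p9 == pytest.approx(
            1.0, abs=1e-12
        )

    def test_invalid_tree_rejected(self):
        with pytest.raises(ValidationError):
            ProbabilityTree(p1=0.6, p2=0.6, p3=0.5, p4=0.5,
                            p5=0.2, p6=0.2, p7=0.2, p8=0.2, p9=0.2)


class TestComputeFunding:
    def test_single_drg_arithmetic(self):
        table = _table({"T": {"371": 2}})
        tariffs = TariffTable(tariffs={"371": 1000.0}, currency="EUR")
        summary = compute_funding(table, tariffs)
        assert summary.cs_funding("T") == 2000.0
        assert summary.vaginal_funding("T") == 0.0

    def test_nok_tariffs_converted(self):
        table = _table({"T": {"373": 3}})
        tariffs = TariffTable(tariffs={"373": 9332.5}, currency="NOK")
        summary = compute_funding(table, tariffs, CurrencyConfig(9.3325))
        assert summary.vaginal_funding("T") == pytest.approx(3000.0)

    def test_missing_tariff_names_drg(self):
        table = _table({"T": {"374": 1}})
        with pytest.raises(ValidationError, match="374"):
            compute_funding(table, TariffTable(tariffs={"373": 1.0}))

    @given(row=count_row, scale=st.integers(2, 5))
    @settings(deadline=None)
    def test_linearity_in_counts(self, row, scale):
        tariffs = TariffTable(tariffs={d: 100.0 + i for i, d in enumerate(DRG_CODES)})
        base = compute_funding(_table({"T": row}), tariffs)
        scaled = compute_funding(
            _table({"T": {d: scale * v for d, v in row.items()}}), tariffs
        )
        assert scaled.cs_funding("T") == pytest.approx(scale * base.cs_funding("T"))
        assert scaled.vaginal_funding("T") == pytest.approx(
            scale * base.vaginal_funding("T")
        )


class TestFundingMeans:
    def test_fixture_means_match_published_figures(self, table1, table2):
        mean_cs, mean_vaginal = funding_means(table2, table1)
        assert mean_cs == pytest.approx(6_389_323 / 850)
        assert mean_vaginal == pytest.approx(9_962_012 / 4010)
        assert round(mean_cs) == 7517
        assert round(mean_vaginal) == 2484

    def test_unit_counts(self):
        from drgcap import FundingTable

        table = _table({"T": {"370": 1, "373": 1}})
        means = funding_means(FundingTable(funding={"T": (100.0, 100.0)}), table)
        assert means == (100.0, 100.0)


class TestCurrency:
    def test_reference_rate(self):
        assert convert_currency(9.3325, "NOK", "EUR") == pytest.approx(1.0)
        assert convert_currency(0.0, "NOK", "EUR") == 0.0

    @given(amount=st.floats(1e-6, 1e9, allow_nan=False))
    @settings(deadline=None)
    def test_round_trip_identity(self, amount):
        back = convert_currency(
            convert_currency(amount, "EUR", "NOK"), "NOK", "EUR"
        )
        assert math.isclose(back, amount, rel_tol=1e-12)

    def test_same_currency_identity(self):
        assert convert_currency(7.0, "EUR", "EUR") == 7.0

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValidationError):
            CurrencyConfig(0.0)
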