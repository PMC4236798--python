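"""Univariate OR screening: exact tables, thresholds, poolability."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import edrisk
from edrisk.catalog import Item, ItemCatalog, default_catalog
from edrisk.errors import ConfigurationError, DataError, UndefinedOddsRatioError
from edrisk.screening import (
    NEUTRAL,
    PROTECTIVE,
    RISK,
    ScreeningConfig,
    TwoByTwoTable,
    build_table,
    classify_item,
    dichotomize,
    odds_ratio,
    poolability_check,
    screen_all,
)
from edrisk.simulate import CohortSpec, SimulationConfig, generate_cohort, split_derivation_validation

from conftest import dataset_from_table, make_dataset


class TestBuildTable:
    def test_hand_counts(self, six_record_dataset):
        t = build_table(six_record_dataset, "x", "derivation")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)
        assert t.total == 6

    def test_empty_split_is_error(self, six_record_dataset):
        with pytest.raises(DataError, match="empty"):
            build_table(six_record_dataset, "x", "validation")

    def test_constant_zero_item_gives_empty_exposed_row(self):
        rows = [(0, 0, 1, "derivation"), (0, 0, 0, "derivation")]
        t = build_table(make_dataset(rows), "x", "derivation")
        assert t.a == 0 and t.b == 0 and t.c + t.d == 2

    def test_unknown_item_rejected(self, six_record_dataset):
        with pytest.raises(DataError, match="unknown item"):
            build_table(six_record_dataset, "nope", "derivation")


class TestOddsRatio:
    def test_cross_product(self):
        assert odds_ratio(TwoByTwoTable(20, 10, 40, 80)) == pytest.approx(4.0)
        assert odds_ratio(TwoByTwoTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_continuity_correction_on_zero_cell(self):
        # (0,10,5,85) -> all cells +0.5 -> (0.5*85.5)/(10.5*5.5)
        expected = (0.5 * 85.5) / (10.5 * 5.5)
        assert odds_ratio(TwoByTwoTable(0, 10, 5, 85)) == pytest.approx(expected)
        assert expected == pytest.approx(0.7403, abs=5e-5)

    def test_no_correction_when_all_cells_positive(self):
        assert odds_ratio(TwoByTwoTable(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_all_zero_cells_undefined(self):
        with pytest.raises(DataError):
            TwoByTwoTable(0, 0, 0, 0)

    def test_symmetry_under_double_swap(self):
        # swapping rows and columns simultaneously leaves the OR unchanged
        assert odds_ratio(TwoByTwoTable(7, 3, 2, 9)) == pytest.approx(
            odds_ratio(TwoByTwoTable(9, 2, 3, 7)))

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30),
           st.integers(1, 30), st.integers(1, 5))
    def test_invariant_under_record_duplication(self, a, b, c, d, k):
        base = odds_ratio(TwoByTwoTable(a, b, c, d))
        dup = odds_ratio(TwoByTwoTable(a * k, b * k, c * k, d * k))
        assert dup == pytest.approx(base, rel=1e-12)


class TestClassify:
    @pytest.mark.parametrize(
        "ord_, orv, expected",
        [
            (1.44, 1.58, RISK),        # alcohol/drug-treatment-like pair
            (0.66, 0.67, PROTECTIVE),  # day-care-like pair
            (1.45, 1.10, NEUTRAL),     # fails validation confirmation
            (1.30, 1.30, RISK),        # threshold met exactly
            (0.75, 0.75, PROTECTIVE),  # threshold met exactly
            (1.29, 2.00, NEUTRAL),
            (0.76, 0.10, NEUTRAL),
        ],
    )
    def test_dual_sample_rule(self, ord_, orv, expected):
        assert classify_item(ord_, orv) == expected

    def test_derivation_only_switch(self):
        cfg = ScreeningConfig(require_validation_confirmation=False)
        assert classify_item(1.45, 1.10, cfg) == RISK

    def test_nonfinite_or_rejected(self):
        with pytest.raises(DataError):
            classify_item(float("inf"), 1.0)
        with pytest.raises(DataError):
            classify_item(1.5, float("nan"))

    def test_threshold_order_enforced(self):
        with pytest.raises(ConfigurationError):
            ScreeningConfig(risk_threshold=0.9)


def brute_force_or(dataset, item_id, split_label, correction=0.5):
    """Independent oracle: pure-python loop over records."""
    a = b = c = d = 0
    for _, row in dataset[dataset["split"] == split_label].iterrows():
        if row[item_id] == 1:
            if row["outcome"] == 1:
                a += 1
            else:
                b += 1
        else:
            if row["outcome"] == 1:
                c += 1
            else:
                d += 1
    if min(a, b, c, d) == 0:
        a, b, c, d = (v + correction for v in (a, b, c, d))
    if b * c == 0:
        return None
    return (a * d) / (b * c)


def test_or_matches_bruteforce_on_random_small_datasets():
    rng = np.random.default_rng(202)
    for _ in range(40):
        n = int(rng.integers(4, 51))
        rows = [(int(rng.random() < 0.5), 0, int(rng.random() < 0.4), "derivation")
                for _ in range(n)]
        ds = make_dataset(rows)
        expected = brute_force_or(ds, "x", "derivation")
        table = build_table(ds, "x", "derivation")
        if expected is None:
            with pytest.raises(UndefinedOddsRatioError):
                odds_ratio(table)
        else:
            assert odds_ratio(table) == expected


class TestScreenAll:
    def test_identical_splits_give_identical_ors(self):
        ds = dataset_from_table(12, 8, 9, 21, split="derivation")
        dup = ds.copy()
        dup["split"] = "validation"
        dup["person_id"] = dup["person_id"] + "v"
        both = pd.concat([ds, dup], ignore_index=True)
        catalog = ItemCatalog([Item("x", "disease", 0.0, 0.5)])
        res = screen_all(both, catalog)
        row = res.table.iloc[0]
        assert row["or_derivation"] == pytest.approx(row["or_validation"])

    def test_all_null_catalog_mostly_neutral(self):
        cfg = SimulationConfig(
            n_persons=50_000,
            cohorts=[CohortSpec("c1", -0.7, 1.0)],
            catalog=edrisk.all_null_catalog(),
            beta_prior_use=0.0,
            seed=13,
        )
        ds = split_derivation_validation(generate_cohort(cfg), 0.5, seed=1)
        res = screen_all(ds, edrisk.all_null_catalog())
        neutral = (res.table["classification"] == NEUTRAL).mean()
        assert neutral >= 0.95

    def test_serialization_round_trip(self, tmp_path):
        ds = dataset_from_table(12, 8, 9, 21)
        dup = ds.copy()
        dup["split"] = "validation"
        dup["person_id"] = dup["person_id"] + "v"
        both = pd.concat([ds, dup], ignore_index=True)
        catalog = ItemCatalog([Item("x", "disease", 0.0, 0.5)])
        res = screen_all(both, catalog)
        res.to_tsv(tmp_path / "s.tsv")
        res.to_json(tmp_path / "s.json")
        back = pd.read_csv(tmp_path / "s.tsv", sep="\t")
        assert list(back.columns) == ["item_id", "domain", "or_derivation",
                                      "or_validation", "classification"]


class TestPoolability:
    @staticmethod
    def _cohorts(flip_item=None, n=40_000):
        out = {}
        for i, label in enumerate(["c1", "c2", "c3"]):
            if flip_item and label == "c3":
                items = []
                for it in default_catalog():
                    beta = -it.true_beta if it.item_id == flip_item else it.true_beta
                    items.append(Item(it.item_id, it.domain, beta, it.prevalence))
                catalog = ItemCatalog(items)
            else:
                catalog = default_catalog()
            cfg = SimulationConfig(
                n_persons=n,
                cohorts=[CohortSpec(label, -2.0, 1.0)],
                catalog=catalog,
                beta_prior_use=math.log(4.0),
                seed=100 + i,
            )
            out[label] = generate_cohort(cfg)
        return out

    def test_homogeneous_cohorts_pass(self):
        table, verdict = poolability_check(self._cohorts())
        assert verdict is True
        assert len(table) == 3 * 5

    def test_sign_flipped_cohort_fails(self):
        _, verdict = poolability_check(self._cohorts(flip_item="pneumonia"))
        assert verdict is False

    def test_single_cohort_vacuously_consistent(self):
        cohorts = self._cohorts(n=5_000)
        _, verdict = poolability_check({"c1": cohorts["c1"]})
        assert verdict is True

    def test_missing_probe_item_rejected(self):
        cohorts = self._cohorts(n=2_000)
        bad = cohorts["c1"].drop(columns=["pneumonia"])
        with pytest.raises(DataError, match="pneumonia"):
            poolability_check({"c1": bad})


def test_dichotomize_rule_table_hook():
    df = pd.DataFrame({"person_id": ["a", "b", "c"], "adl_score": [0, 3, 5]})
    out = dichotomize(df, {"adl_impaired": ("adl_score", 3)})
    assert out["adl_impaired"].tolist() == [0, 1, 1]
    with pytest.raises(DataError):
        dichotomize(df, {"x": ("missing_col", 1)})
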