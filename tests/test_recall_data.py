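"""Recall aggregation, flour fractions, and group flour summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import calfort as cf
from calfort.recall_data import (
    DataValidationError,
    FlourMap,
    RecallRecord,
    Subject,
    daily_totals,
    flour_summary,
    read_recalls,
    read_subjects,
)


@pytest.fixture
def fmap():
    return FlourMap(
        {
            "mixed_cake": [("rice", 0.30), ("wheat", 0.40)],
            "flour": [("wheat", 1.0)],
            "bread": [("wheat", 0.65)],
            "milk": [],
        }
    )


class TestFlourFraction:
    def test_mixed_flours_sum(self, fmap):
        # 30% rice flour + 40% wheat flour: all of it fortifiable, 70%
        assert fmap.fraction("mixed_cake") == pytest.approx(0.70)

    def test_pure_flour(self, fmap):
        assert fmap.fraction("flour") == 1.0

    def test_no_flour_and_unmapped(self, fmap):
        assert fmap.fraction("milk") == 0.0
        assert fmap.fraction("mystery_food") == 0.0
        assert "mystery_food" in fmap.unmapped_codes

    def test_type_filter(self, fmap):
        assert fmap.fraction("mixed_cake", flour_types=["wheat"]) == pytest.approx(0.40)
        assert fmap.fraction("mixed_cake", flour_types=["maize"]) == 0.0

    def test_fractions_over_one_rejected(self):
        with pytest.raises(DataValidationError):
            FlourMap({"bad": [("wheat", 0.7), ("rice", 0.5)]})

    def test_unknown_flour_type_rejected(self):
        with pytest.raises(DataValidationError):
            FlourMap({"bad": [("quinoa", 0.5)]})


SUBJ = [Subject("s1", 30.0, "female")]


class TestDailyTotals:
    def test_hand_sum(self, fmap):
        records = [
            RecallRecord("s1", 1, "bread", 100.0, 30.0),
            RecallRecord("s1", 1, "milk", 200.0, 240.0),
        ]
        daily = daily_totals(records, SUBJ, fmap)
        assert len(daily) == 1
        assert daily.loc[0, "calcium_mg"] == pytest.approx(270.0)
        assert daily.loc[0, "flour_g"] == pytest.approx(65.0)

    def test_tablet_supplement_counts_calcium_not_flour(self, fmap):
        records = [
            RecallRecord("s1", 1, "flour", 1.0, 500.0, is_tablet_supplement=True)
        ]
        daily = daily_totals(records, SUBJ, fmap)
        assert daily.loc[0, "calcium_mg"] == pytest.approx(500.0)
        assert daily.loc[0, "flour_g"] == 0.0

    def test_powder_supplement_counts_both(self, fmap):
        records = [RecallRecord("s1", 1, "flour", 10.0, 300.0)]
        daily = daily_totals(records, SUBJ, fmap)
        assert daily.loc[0, "calcium_mg"] == pytest.approx(300.0)
        assert daily.loc[0, "flour_g"] == pytest.approx(10.0)

    def test_no_records_no_rows(self, fmap):
        assert daily_totals([], SUBJ, fmap).empty

    def test_orphan_subject_rejected(self, fmap):
        with pytest.raises(DataValidationError, match="ghost"):
            daily_totals([RecallRecord("ghost", 1, "bread", 10, 5)], SUBJ, fmap)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        amounts=st.lists(
            st.tuples(
                st.floats(0, 500, allow_nan=False),
                st.floats(0, 800, allow_nan=False),
            ),
            min_size=1,
            max_size=8,
        ),
        split=st.floats(0.01, 0.99),
    )
    def test_aggregation_additive_and_order_independent(self, amounts, split):
        """Splitting any record in two and shuffling leaves totals unchanged."""
        fmap = FlourMap({"bread": [("wheat", 0.65)]})
        records = [
            RecallRecord("s1", 1, "bread", a, c) for a, c in amounts
        ]
        halves = [
            RecallRecord("s1", 1, "bread", a * f, c * f)
            for a, c in amounts
            for f in (split, 1.0 - split)
        ]
        t1 = daily_totals(records, SUBJ, fmap)
        t2 = daily_totals(list(reversed(halves)), SUBJ, fmap)
        assert t1.loc[0, "calcium_mg"] == pytest.approx(t2.loc[0, "calcium_mg"])
        assert t1.loc[0, "flour_g"] == pytest.approx(t2.loc[0, "flour_g"])

    def test_flour_never_exceeds_total_grams(self, fmap):
        rng = np.random.default_rng(5)
        records = [
            RecallRecord("s1", 1, code, float(a), 10.0)
            for code, a in zip(
                rng.choice(["bread", "flour", "milk", "mixed_cake"], 30),
                rng.uniform(0, 300, 30),
            )
        ]
        daily = daily_totals(records, SUBJ, fmap)
        total_g = sum(r.amount_g for r in records)
        assert daily.loc[0, "flour_g"] <= total_g


def _mk_subjects(weights):
    return [
        Subject(f"s{i}", 30.0, "female", weight=w) for i, w in enumerate(weights)
    ]


def _mk_daily(subjects, flours):
    import pandas as pd

    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "day": 1,
            "calcium_mg": 100.0,
            "flour_g": flours,
        }
    )


class TestFlourSummary:
    def test_all_consumers(self):
        subs = _mk_subjects([1, 1, 1])
        s = flour_summary(_mk_daily(subs, [10.0, 20.0, 30.0]), subs)
        assert s.pct_consuming == pytest.approx(100.0)

    def test_equal_weights_hand_computation(self):
        subs = _mk_subjects([1, 1])
        s = flour_summary(_mk_daily(subs, [0.0, 100.0]), subs)
        assert s.pct_consuming == pytest.approx(50.0)
        assert s.mean_flour_g == pytest.approx(50.0)
        assert s.sd_flour_g == pytest.approx(50.0)  # population SD

    def test_weighted_mean(self):
        subs = _mk_subjects([1, 3])
        s = flour_summary(_mk_daily(subs, [0.0, 100.0]), subs)
        assert s.pct_consuming == pytest.approx(75.0)
        assert s.mean_flour_g == pytest.approx(75.0)

    def test_unit_weights_equal_unweighted(self):
        rng = np.random.default_rng(11)
        flours = rng.gamma(2, 40, 20)
        subs = _mk_subjects(np.ones(20))
        s = flour_summary(_mk_daily(subs, flours), subs)
        assert s.mean_flour_g == pytest.approx(flours.mean())
        assert s.sd_flour_g == pytest.approx(flours.std())

    def test_uses_first_day_only(self):
        import pandas as pd

        subs = _mk_subjects([1.0])
        daily = pd.DataFrame(
            {
                "subject_id": ["s0", "s0"],
                "day": [1, 2],
                "calcium_mg": [100.0, 100.0],
                "flour_g": [0.0, 80.0],
            }
        )
        s = flour_summary(daily, subs)
        assert s.pct_consuming == 0.0
        assert s.mean_flour_g == 0.0


class TestReaders:
    def test_roundtrip(self, tmp_path, fmap):
        from calfort.recall_data import recalls_to_csv, subjects_to_csv

        subjects = [
            Subject("a", 25.0, "female", pregnant=True, weight=1.5),
            Subject("b", 3.0, "male"),
        ]
        records = [
            RecallRecord("a", 1, "bread", 120.0, 40.0),
            RecallRecord("b", 2, "milk", 200.0, 230.0, is_tablet_supplement=False),
        ]
        subjects_to_csv(subjects, tmp_path / "s.csv")
        recalls_to_csv(records, tmp_path / "r.csv")
        assert read_subjects(tmp_path / "s.csv") == subjects
        assert read_recalls(tmp_path / "r.csv") == records

    def test_line_numbered_errors(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text(
            "subject_id,age_years,sex,pregnant,weight\n"
            "a,25,female,false,1.0\n"
            "b,-3,male,false,1.0\n"
        )
        with pytest.raises(DataValidationError, match="line 3"):
            read_subjects(path)

    def test_duplicate_subject_ids_rejected(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text(
            "subject_id,age_years,sex,pregnant,weight\n"
            "a,25,female,false,1.0\n"
            "a,30,female,false,1.0\n"
        )
        with pytest.raises(DataValidationError, match="duplicate"):
            read_subjects(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("subject_id,day\na,1\n")
        with pytest.raises(DataValidationError, match="missing columns"):
            read_recalls(path)
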