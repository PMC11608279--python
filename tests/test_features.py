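"""Feature building, prevalence filtering and row deduplication."""

import numpy as np
import pandas as pd
import pytest

from hicost import build_features, deduplicate, filter_low_prevalence
from hicost.claims import DEPARTMENTS
from hicost.features import DEFAULT_AGE_BINS, FeatureMatrix


def _fm(matrix: pd.DataFrame, source: str = "ADRG") -> FeatureMatrix:
    return FeatureMatrix(
        matrix=matrix,
        sources={c: source for c in matrix.columns},
        prevalence=matrix.mean(),
    )


@pytest.fixture()
def single_admission_setup(maps):
    patients = pd.DataFrame(
        {"patient_id": ["A"], "age": [50], "gender": ["male"], "poverty": [False]}
    )
    enc = pd.DataFrame(
        {
            "encounter_id": ["e1"],
            "patient_id": ["A"],
            "encounter_type": ["inpatient"],
            "year": [2019],
            "principal_dx": ["N20001"],  # urinary calculi
            "department": ["surgery"],
            "in_county": [True],
            "los_days": [5],
            "total_spend": [5000.0],
            "oop_spend": [2000.0],
        }
    )
    summaries = pd.DataFrame({"patient_id": ["A"], "high_cost": [True]})
    return summaries, enc, patients


class TestBuild:
    def test_single_admission_sets_expected_columns(self, single_admission_setup, maps):
        summaries, enc, patients = single_admission_setup
        fm = build_features(summaries, enc, enc, patients, maps["adrg"], maps["elixhauser"])
        row = fm.matrix.loc["A"]
        on = set(row[row == 1].index)
        assert "department: surgery" in on
        assert "adrg: urinary calculi, obstruction, and urethral stricture" in on
        # demographics: male, 45-64
        assert "age_45_64" in on and "female" not in on
        # nothing else from ADRG/department sources
        extra = {
            c for c in on
            if fm.sources[c] in ("ADRG", "department")
        } - {"department: surgery", "adrg: urinary calculi, obstruction, and urethral stricture"}
        assert not extra

    def test_chronic_flag_from_lookback_year_only(self, single_admission_setup, maps):
        summaries, enc, patients = single_admission_setup
        prior = enc.assign(
            encounter_id="e0", year=2017, encounter_type="outpatient",
            principal_dx="I10002", los_days=0,
        )
        enc_all = pd.concat([prior, enc], ignore_index=True)
        fm = build_features(summaries, enc, enc_all, patients, maps["adrg"], maps["elixhauser"])
        assert fm.matrix.loc["A", "comorbidity: hypertension, uncomplicated"] == 1
        # but the 2017 dx never sets an active-diagnosis (index-year) flag
        assert fm.matrix.loc["A", "adrg: hypertension"] == 0

    def test_column_count_from_maps(self, features20k, maps):
        fm = features20k
        n_demo = 1 + len(DEFAULT_AGE_BINS)
        assert len(fm.columns_of("demographic")) == n_demo
        assert len(fm.columns_of("department")) <= len(DEPARTMENTS)
        assert set(fm.columns_of("ADRG")) <= {
            f"adrg: {c}" for c in maps["adrg"].categories
        }
        assert set(fm.columns_of("comorbidity")) <= {
            f"comorbidity: {c}" for c in maps["elixhauser"].categories
        }

    def test_order_insensitive(self, single_admission_setup, maps):
        summaries, enc, patients = single_admission_setup
        enc2 = pd.concat([enc, enc.assign(encounter_id="e2", principal_dx="I20003")])
        fm_a = build_features(summaries, enc2, enc2, patients, maps["adrg"], maps["elixhauser"])
        rev = enc2.iloc[::-1]
        fm_b = build_features(summaries, rev, rev, patients, maps["adrg"], maps["elixhauser"])
        pd.testing.assert_frame_equal(fm_a.matrix, fm_b.matrix)


class TestFilter:
    def _matrix_with_prevalence(self, p, n=1000):
        col = np.zeros(n, dtype=np.int8)
        col[: int(round(p * n))] = 1
        return pd.DataFrame({"x": col}, index=[f"p{i}" for i in range(n)])

    @pytest.mark.parametrize(
        "source, p, kept",
        [
            ("ADRG", 0.009, False),
            ("ADRG", 0.010, True),       # "less than" is strict
            ("comorbidity", 0.0009, False),
            ("comorbidity", 0.0010, True),
            ("demographic", 0.0001, True),  # never dropped
            ("department", 0.0001, True),
        ],
    )
    def test_threshold_boundaries(self, source, p, kept):
        n = 10_000
        fm = _fm(self._matrix_with_prevalence(p, n), source)
        if not kept:
            with pytest.raises(ValueError, match="every column"):
                filter_low_prevalence(fm)
        else:
            assert list(filter_low_prevalence(fm).matrix.columns) == ["x"]

    def test_idempotent(self, features20k):
        again = filter_low_prevalence(features20k)
        pd.testing.assert_frame_equal(again.matrix, features20k.matrix)

    def test_engineered_survivor_count(self):
        # 30 ADRG columns: 12 at 5% prevalence, 18 below 1% -> exactly 12 survive
        n = 1000
        cols = {}
        for i in range(12):
            c = np.zeros(n, dtype=np.int8); c[:50] = 1; cols[f"common{i}"] = c
        for i in range(18):
            c = np.zeros(n, dtype=np.int8); c[:5] = 1; cols[f"rare{i}"] = c
        fm = _fm(pd.DataFrame(cols, index=[f"p{i}" for i in range(n)]))
        out = filter_low_prevalence(fm)
        assert out.matrix.shape[1] == 12
        assert all(c.startswith("common") for c in out.matrix.columns)


class TestDedup:
    def test_identical_rows_collapse(self):
        m = pd.DataFrame({"a": [1, 1], "b": [0, 0]}, index=["p1", "p2"])
        dd = deduplicate(_fm(m))
        assert len(dd.unique) == 1
        assert dd.multiplicity.iloc[0] == 2
        assert set(dd.representative.index) == {"p1", "p2"}

    def test_all_distinct_identity(self):
        m = pd.DataFrame({"a": [1, 0, 1], "b": [0, 0, 1]}, index=["p1", "p2", "p3"])
        dd = deduplicate(_fm(m))
        assert len(dd.unique) == 3
        assert (dd.multiplicity == 1).all()

    def test_expand_reproduces_row_multiset(self, features20k, dedup20k):
        expanded = dedup20k.expand()
        orig = features20k.matrix
        assert dedup20k.multiplicity.sum() == len(orig)
        a = orig.sort_values(list(orig.columns)).reset_index(drop=True)
        b = expanded[orig.columns].sort_values(list(orig.columns)).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
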