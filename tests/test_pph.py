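"""Preventable-hospitalization flagging, PIC accounting, report shares."""

import numpy as np
import pandas as pd
import pytest

from hicost import compute_pic, flag_pph, share, subgroup_report
from hicost.codes import CodeMap


@pytest.fixture()
def admissions():
    rows = [
        ("e1", "A", "inpatient", "I50900"),   # heart failure -> flaggable
        ("e2", "A", "inpatient", "S72000"),   # fracture -> not
        ("e3", "B", "inpatient", "E11901"),   # diabetes -> flaggable
        ("e4", "B", "outpatient", "I50900"),  # outpatient: never flagged
        ("e5", "C", "inpatient", "C34900"),   # tumour -> not
    ]
    df = pd.DataFrame(rows, columns=["encounter_id", "patient_id", "encounter_type", "principal_dx"])
    df["total_spend"] = [500.0, 300.0, 800.0, 60.0, 4000.0]
    df["year"] = 2019
    return df


class TestFlag:
    def test_prefix_flagging(self, admissions, maps):
        flags = flag_pph(admissions, maps["pqi"]).set_index("encounter_id")
        assert flags.loc["e1", "pph"] and flags.loc["e1", "matched_category"] == "heart failure"
        assert flags.loc["e1", "matched_prefix"] == "I50"
        assert not flags.loc["e2", "pph"]
        assert flags.loc["e3", "pph"]

    def test_outpatient_never_flagged(self, admissions, maps):
        flags = flag_pph(admissions, maps["pqi"]).set_index("encounter_id")
        assert not flags.loc["e4", "pph"]
        assert pd.isna(flags.loc["e4", "matched_category"])

    def test_monotone_in_code_list(self, admissions, maps):
        small = CodeMap("pqi-small", {"I50": "heart failure"})
        flags_small = flag_pph(admissions, small)
        flags_full = flag_pph(admissions, maps["pqi"])
        was_flagged = set(flags_small.loc[flags_small["pph"], "encounter_id"])
        now_flagged = set(flags_full.loc[flags_full["pph"], "encounter_id"])
        assert was_flagged <= now_flagged

    def test_exclusion_hook(self, admissions, maps):
        excl = CodeMap("excl", {"I509": "excluded"})
        flags = flag_pph(admissions, maps["pqi"], exclusions=excl).set_index("encounter_id")
        assert not flags.loc["e1", "pph"]
        assert flags.loc["e3", "pph"]

    def test_planted_rate_recovered(self, pop20k, maps):
        # default chronic-disease group plants 25% ambulatory-care-sensitive admissions
        patients, encounters, latent = pop20k
        members = latent.loc[latent["latent_group"] == "chronic disease", "patient_id"]
        adm = encounters[
            (encounters["encounter_type"] == "inpatient")
            & encounters["patient_id"].isin(members)
        ]
        flags = flag_pph(adm, maps["pqi"])
        p, n = 0.25, len(flags)
        se = np.sqrt(p * (1 - p) / n)
        assert flags["pph"].mean() == pytest.approx(p, abs=3 * se)


class TestPIC:
    def test_per_patient_sum(self, admissions, maps):
        flags = flag_pph(admissions, maps["pqi"])
        pic = compute_pic(flags, admissions)
        assert pic["A"] == pytest.approx(500.0)  # e1 only; e2 unflagged
        assert pic["B"] == pytest.approx(800.0)  # outpatient e4 excluded
        assert pic["C"] == 0.0

    def test_conservation(self, pop20k, maps):
        _, encounters, _ = pop20k
        enc19 = encounters[encounters["year"] == 2019]
        flags = flag_pph(enc19, maps["pqi"])
        pic = compute_pic(flags, enc19)
        flagged_total = enc19.loc[
            enc19["encounter_id"].isin(flags.loc[flags["pph"], "encounter_id"]),
            "total_spend",
        ].sum()
        assert pic.sum() == pytest.approx(flagged_total)

    def test_pic_bounded_by_inpatient_spend(self, pop20k, summaries20k, maps):
        _, encounters, _ = pop20k
        enc19 = encounters[encounters["year"] == 2019]
        pic = compute_pic(flag_pph(enc19, maps["pqi"]), enc19)
        joined = summaries20k.set_index("patient_id").join(pic.rename("pic")).fillna(0)
        assert (joined["pic"] <= joined["inpatient_spend"] + 1e-9).all()


class TestShare:
    @pytest.mark.parametrize(
        "num, den, dp, expected",
        [
            (12_095, 32_108, 2, 37.67),
            (2_264, 2_722, 0, 83.0),
            (2_236, 2_264, 0, 99.0),
            (2_831, 18_434, 2, 15.36),
            (5_489, 18_434, 2, 29.78),
            (1, 8, 2, 12.5),
            (1, 3, 0, 33.0),
        ],
    )
    def test_printed_percentages(self, num, den, dp, expected):
        assert share(num, den, dp) == expected

    def test_half_up_not_bankers(self):
        assert share(125, 1000, 1) == 12.5
        assert share(1250, 100000, 2) == 1.25
        assert share(125, 10000, 2) == 1.25
        assert share(25, 1000, 1) == 2.5
        assert share(5, 1000, 1) == 0.5
        assert share(45, 1000, 0) == 5.0  # 4.5 rounds up, not to even

    def test_zero_denominator_blank(self):
        assert share(5, 0) is None


class TestSubgroupReport:
    def test_single_patient_subgroup(self, admissions, maps):
        summaries = pd.DataFrame(
            {
                "patient_id": ["A", "B", "C"],
                "total_spend": [800.0, 860.0, 4000.0],
                "inpatient_spend": [800.0, 800.0, 4000.0],
                "oop_spend": [300.0, 200.0, 1500.0],
                "admissions": [2, 1, 1],
                "avg_los": [5.0, 3.0, 7.0],
                "outpatient_visits": [0, 1, 0],
            }
        )
        pic = compute_pic(flag_pph(admissions, maps["pqi"]), admissions)
        labels = pd.Series(["x", "x", "solo"], index=["A", "B", "C"], name="subgroup")
        rep = subgroup_report(labels, summaries, pic).set_index("subgroup")
        solo = rep.loc["solo"]
        assert solo["n_patients"] == 1
        assert solo["admissions_mean"] == 1
        assert pd.isna(solo["admissions_sd"])  # SD undefined for n=1
        assert solo["pic_pct_of_total"] == 0.0  # tumour admission not preventable
        assert rep.loc["x", "pic_pct_of_total"] == pytest.approx(
            100 * (500 + 800) / (800 + 860), abs=0.005
        )

    def test_invariant_pic_le_inpatient_le_100(self, summaries20k, labels20k, pop20k, maps):
        _, encounters, _ = pop20k
        enc19 = encounters[encounters["year"] == 2019]
        pic = compute_pic(flag_pph(enc19, maps["pqi"]), enc19)
        subgroups = labels20k.map(lambda c: "noise" if c == -1 else f"cluster {c}")
        rep = subgroup_report(subgroups, summaries20k, pic)
        assert (rep["pic_pct_of_total"] <= rep["inpatient_pct_of_total"]).all()
        assert rep["inpatient_pct_of_total"].between(0, 100).all()
        assert rep["oop_pct_of_total"].between(0, 100).all()

    def test_size_weighted_means_recover_cohort_mean(self, summaries20k, labels20k, pop20k, maps):
        _, encounters, _ = pop20k
        enc19 = encounters[encounters["year"] == 2019]
        pic = compute_pic(flag_pph(enc19, maps["pqi"]), enc19)
        subgroups = labels20k.map(lambda c: "noise" if c == -1 else f"cluster {c}")
        rep = subgroup_report(subgroups, summaries20k, pic)
        cohort = summaries20k.set_index("patient_id").loc[labels20k.index]
        from hicost import cny_to_usd

        weighted = (rep["n_patients"] * rep["total_spend_mean_usd"]).sum() / rep["n_patients"].sum()
        assert weighted == pytest.approx(cny_to_usd(cohort["total_spend"].mean()), rel=1e-9)
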