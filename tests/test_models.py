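"""Candidate motility models, AIC arithmetic and selection rules."""

import numpy as np
import pandas as pd
import pytest

from tigermove import (
    REFERENCE_EDGE_DENSITY_AIC,
    cohort_ttest_fl_by_sex,
    fit_candidates,
    model_selection_table,
    select_model,
    smooth_summary,
)

# the reference candidate set's published deviance-explained column
REFERENCE_DEVIANCE = {
    "ED ~ s(FL) + Island": 46.40,
    "ED ~ s(FL)": 42.40,
    "ED ~ s(FL, by=Sex) + Sex + Island": 50.50,
    "ED ~ s(FL, by=Sex) + Island": 46.30,
    "ED ~ s(FL) + Sex + Island": 47.40,
    "ED ~ s(FL, by=Sex) + Sex": 45.20,
    "ED ~ s(FL) + Sex": 42.30,
    "ED ~ Sex": 0.53,
    "ED ~ Island": 0.32,
}


def synthetic_motility(seed=0, n=60, sex_specific=True):
    rng = np.random.default_rng(seed)
    sex = rng.choice(["F", "M"], size=n, p=[0.75, 0.25])
    fl = np.where(
        sex == "M", rng.uniform(140, 253, n), rng.uniform(91, 300, n)
    )
    island = rng.choice(["NP", "GE"], size=n)
    male = 0.02 + 0.2 * (fl - 140) / 113
    female = 0.05 + 0.25 * np.exp(-0.5 * ((fl - 237.5) / 35) ** 2)
    mean = np.where(sex == "M", male, female) if sex_specific else male
    ed = np.clip(mean + rng.normal(0, 0.03, n), 0, 1)
    return pd.DataFrame(
        {
            "edge_density": ed,
            "fl_first_detection_cm": fl,
            "sex": sex,
            "island": island,
        }
    )


class TestSelectionTableArithmetic:
    def test_reference_delta_and_weights(self):
        table = model_selection_table(REFERENCE_EDGE_DENSITY_AIC)
        by_id = table.set_index("model_id")
        printed_delta = {
            "ED ~ s(FL) + Island": 0.00,
            "ED ~ s(FL)": 0.13,
            "ED ~ s(FL, by=Sex) + Sex + Island": 0.82,
            "ED ~ s(FL, by=Sex) + Island": 1.26,
            "ED ~ s(FL) + Sex + Island": 1.26,
            "ED ~ s(FL, by=Sex) + Sex": 1.96,
            "ED ~ s(FL) + Sex": 2.02,
            "ED ~ Sex": 13.16,
            "ED ~ Island": 13.23,
        }
        printed_weight = {
            "ED ~ s(FL) + Island": 0.23,
            "ED ~ s(FL)": 0.21,
            "ED ~ s(FL, by=Sex) + Sex + Island": 0.15,
            "ED ~ s(FL, by=Sex) + Island": 0.12,
            "ED ~ s(FL) + Sex + Island": 0.12,
            "ED ~ s(FL, by=Sex) + Sex": 0.09,
            "ED ~ s(FL) + Sex": 0.08,
            "ED ~ Sex": 0.00,
            "ED ~ Island": 0.00,
        }
        for mid, want in printed_delta.items():
            # agreement at the printed 2-decimal precision
            assert by_id.loc[mid, "delta_aic"] == pytest.approx(want, abs=0.0101)
        for mid, want in printed_weight.items():
            assert by_id.loc[mid, "akaike_weight"] == pytest.approx(want, abs=0.005)
        assert by_id["akaike_weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_permutation_invariance(self):
        items = list(REFERENCE_EDGE_DENSITY_AIC.items())
        shuffled = dict(reversed(items))
        a = model_selection_table(REFERENCE_EDGE_DENSITY_AIC)
        b = model_selection_table(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_single_model(self):
        t = model_selection_table({"only": -12.0})
        assert t.loc[0, "delta_aic"] == 0.0
        assert t.loc[0, "akaike_weight"] == 1.0


class TestSelectModel:
    def reference_table(self):
        t = model_selection_table(REFERENCE_EDGE_DENSITY_AIC)
        t["deviance_explained_pct"] = t["model_id"].map(REFERENCE_DEVIANCE)
        return t

    def test_default_rule_picks_sex_specific(self):
        sel = select_model(self.reference_table())
        assert sel["model_id"] == "ED ~ s(FL, by=Sex) + Sex + Island"
        assert sel["delta_aic"] == pytest.approx(0.82, abs=0.011)

    def test_pure_aic_rule(self):
        sel = select_model(self.reference_table(), rule="aic")
        assert sel["model_id"] == "ED ~ s(FL) + Island"

    def test_single_candidate_within_two(self):
        t = model_selection_table({"a": -10.0, "b": -5.0})
        t["deviance_explained_pct"] = [30.0, 60.0]
        assert select_model(t)["model_id"] == "a"

    def test_deviance_tie_breaks_to_lower_aic(self):
        t = model_selection_table({"a": -10.0, "b": -9.5})
        t["deviance_explained_pct"] = [40.0, 40.0]
        assert select_model(t)["model_id"] == "a"


class TestFitCandidates:
    def test_constant_response_explains_nothing(self):
        df = synthetic_motility(seed=1)
        df["edge_density"] = 0.2
        fits = fit_candidates(df)
        for f in fits.values():
            assert f.deviance_explained_pct == pytest.approx(0.0, abs=1e-6)

    def test_mismatched_records_rejected(self):
        f1 = fit_candidates(synthetic_motility(seed=1))
        f2 = fit_candidates(synthetic_motility(seed=2, n=50))
        mixed = {"a": list(f1.values())[0], "b": list(f2.values())[0]}
        with pytest.raises(ValueError, match="different records"):
            model_selection_table(mixed)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_candidates(synthetic_motility(n=6))

    def test_single_sex_drops_sex_models(self):
        df = synthetic_motility(seed=3)
        df["sex"] = "F"
        with pytest.warns(UserWarning, match="single sex"):
            fits = fit_candidates(df)
        assert all("Sex" not in mid for mid in fits)

    def test_male_linear_effect_recovered(self):
        df = synthetic_motility(seed=4)
        fits = fit_candidates(df)
        fit = fits["ED ~ s(FL, by=Sex) + Sex"]
        summ = smooth_summary(fit, df, sex_level="M")
        assert summ["trend_increasing"]
        assert summ["monotone_increasing"]
        assert summ["p_value"] < 0.05

    def test_female_unimodal_peak_recovered(self):
        peaks = []
        for seed in range(10):
            df = synthetic_motility(seed=seed)
            fits = fit_candidates(df)
            summ = smooth_summary(
                fits["ED ~ s(FL, by=Sex) + Sex"], df, sex_level="F"
            )
            if summ["interior_peak_fl_cm"] is not None:
                peaks.append(summ["interior_peak_fl_cm"])
        assert len(peaks) >= 7
        assert abs(np.median(peaks) - 237.5) <= 15.0


class TestCohortTTest:
    def test_identical_distributions(self):
        df = pd.DataFrame(
            {
                "sex": ["F"] * 3 + ["M"] * 3,
                "fl_first_detection_cm": [200.0, 210.0, 220.0] * 2,
            }
        )
        res = cohort_ttest_fl_by_sex(df)
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_degrees_of_freedom_pooled(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "sex": ["F"] * 30 + ["M"] * 9,
                "fl_first_detection_cm": rng.uniform(100, 300, 39),
            }
        )
        assert cohort_ttest_fl_by_sex(df)["df"] == 37

    def test_toy_matches_closed_form(self):
        a = np.array([1.0, 2.0, 3.0])  # female
        b = np.array([2.0, 4.0, 6.0])  # male
        df = pd.DataFrame(
            {"sex": ["F"] * 3 + ["M"] * 3, "fl_first_detection_cm": np.r_[a, b]}
        )
        sp2 = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        sp2 /= 4
        want = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        res = cohort_ttest_fl_by_sex(df)
        assert res["t"] == pytest.approx(want)
        assert res["df"] == 4

    def test_one_sex_missing_rejected(self):
        df = pd.DataFrame({"sex": ["F"] * 5, "fl_first_detection_cm": range(5)})
        with pytest.raises(ValueError):
            cohort_ttest_fl_by_sex(df)
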