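"""Exact tests, logistic odds ratios and the cohort summary table.

Fisher p-values are cross-checked against an independent brute-force
hypergeometric enumeration, and small-sample Mann-Whitney p-values against
an exhaustive enumeration over rank assignments.
"""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fh_triage.association import (ModelSpec, SeparationError, fisher_2x2,
                                   fit_logistic_or, group_summary, icd10_buckets_of,
                                   ihd_model_spec, lipid_or_models, mann_whitney)
from fh_triage.phenotype import DegenerateGroupError
from fh_triage.synthetic import CohortSimParams, generate_cohort


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def mw_p_enumeration(x, y) -> float:
    """Two-sided Mann-Whitney p by enumerating every assignment of the pooled
    values to the two groups (valid with or without ties)."""
    pooled = list(x) + list(y)
    n_x = len(x)

    def u_stat(xs, ys):
        u = 0.0
        for xi in xs:
            for yi in ys:
                u += (xi > yi) + 0.5 * (xi == yi)
        return u

    u_obs = u_stat(x, y)
    mu = n_x * len(y) / 2
    count = 0
    combos = list(itertools.combinations(range(len(pooled)), n_x))
    for idx in combos:
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / len(combos)


class TestFisher:
    def test_printed_table_counts(self):
        res = fisher_2x2(60, 16, 2551, 2219)
        assert res["odds_ratio"] == pytest.approx((60 * 2219) / (16 * 2551), rel=1e-12)
        assert res["odds_ratio"] == pytest.approx(3.26, abs=0.01)
        assert res["p_two_sided"] == pytest.approx(
            fisher_p_enumeration(60, 16, 2551, 2219), rel=1e-6)

    def test_symmetric_table(self):
        res = fisher_2x2(1, 1, 1, 1)
        assert res["odds_ratio"] == 1.0
        assert res["p_two_sided"] == pytest.approx(1.0)

    def test_zero_cell_sentinel_and_exact_tail(self):
        res = fisher_2x2(0, 5, 5, 0)
        assert res["odds_ratio"] == 0.0
        assert res["p_two_sided"] == pytest.approx(fisher_p_enumeration(0, 5, 5, 0), rel=1e-9)
        assert 0 < res["odds_ratio_haldane"] < 1

    def test_infinite_sentinel(self):
        assert fisher_2x2(5, 0, 0, 5)["odds_ratio"] == math.inf

    def test_degenerate_margin_raises(self):
        with pytest.raises(DegenerateGroupError):
            fisher_2x2(0, 0, 3, 4)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            fisher_2x2(-1, 2, 3, 4)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(a=st.integers(0, 15), b=st.integers(0, 15),
           c=st.integers(0, 15), d=st.integers(0, 15))
    def test_matches_enumeration(self, a, b, c, d):
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        res = fisher_2x2(a, b, c, d)
        assert res["p_two_sided"] == pytest.approx(
            fisher_p_enumeration(a, b, c, d), rel=1e-6, abs=1e-12)


class TestMannWhitney:
    def test_identical_multisets(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = mann_whitney(x, list(x))
        assert res["p_two_sided"] > 0.95

    def test_small_sample_matches_enumeration(self):
        x, y = [1.2, 3.4, 2.2, 5.0], [2.5, 4.1, 6.0, 7.5]
        res = mann_whitney(x, y)
        assert res["method"] == "exact"
        assert res["p_two_sided"] == pytest.approx(mw_p_enumeration(x, y), rel=1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(data=st.lists(st.integers(0, 6), min_size=8, max_size=8))
    def test_tied_small_samples_close_to_enumeration(self, data):
        x, y = [float(v) for v in data[:4]], [float(v) for v in data[4:]]
        if len(set(x + y)) < 4:
            return  # the normal approximation is not meant for near-constant data
        # ties force the corrected normal approximation; enumeration bounds it
        res = mann_whitney(x, y)
        assert res["p_two_sided"] == pytest.approx(mw_p_enumeration(x, y), abs=0.12)

    def test_stochastically_larger_group_detected(self):
        rng = np.random.default_rng(10)
        x = rng.normal(1.0, 1.0, 200)
        y = rng.normal(0.0, 1.0, 200)
        assert mann_whitney(x, y)["p_two_sided"] < 1e-6

    def test_empty_group_raises(self):
        with pytest.raises(DegenerateGroupError):
            mann_whitney([], [1.0])


class TestLogistic:
    def test_null_exposure_or_near_one(self):
        cohort, _ = generate_cohort(CohortSimParams(
            n_participants=10_000, true_carrier_or=1.0, carrier_prevalence=0.2, seed=21))
        res = fit_logistic_or(cohort, ihd_model_spec(1))
        se = (math.log(res.ci_high) - math.log(res.odds_ratio)) / 1.959963984540054
        assert abs(math.log(res.odds_ratio)) < 3 * se

    def test_no_covariate_or_equals_sample_or(self):
        rng = np.random.default_rng(5)
        n = 4000
        x = rng.integers(0, 2, n)
        y = (rng.random(n) < np.where(x == 1, 0.55, 0.45)).astype(int)
        df = pd.DataFrame({"y": y, "x": x})
        res = fit_logistic_or(df, ModelSpec("y", "x"))
        a = int(((x == 1) & (y == 1)).sum()); b = int(((x == 1) & (y == 0)).sum())
        c = int(((x == 0) & (y == 1)).sum()); d = int(((x == 0) & (y == 0)).sum())
        assert res.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_perfect_separation_names_covariate(self):
        df = pd.DataFrame({"y": [0, 0, 1, 1], "x": [0.0, 0.1, 5.0, 5.1]})
        with pytest.raises(SeparationError, match="x"):
            fit_logistic_or(df, ModelSpec("y", "x"))

    def test_nonbinary_outcome_rejected(self):
        df = pd.DataFrame({"y": [0, 1, 2, 1], "x": [0, 1, 0, 1]})
        with pytest.raises(ValueError):
            fit_logistic_or(df, ModelSpec("y", "x"))

    def test_exposure_duplicated_in_covariates_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("y", "x", ("x",))

    def test_model2_covariate_set(self):
        spec = ihd_model_spec(2)
        assert set(spec.covariates) == {"sex_male", "age", "bmi", "diabetes",
                                        "smoking_dependent"}

    def test_effect_recovery_model2(self):
        cohort, truth = generate_cohort(CohortSimParams(
            n_participants=30_000, carrier_prevalence=0.1, true_carrier_or=1.5,
            bmi_logor_per_sd=0.2, diabetes_logor=0.3, smoking_logor=0.3, seed=31))
        res = fit_logistic_or(cohort, ihd_model_spec(2))
        se = (math.log(res.ci_high) - math.log(res.odds_ratio)) / 1.959963984540054
        assert abs(math.log(res.odds_ratio) - truth["true_carrier_logor"]) < 3 * se


class TestLipidModels:
    def _frame(self, seed, shift):
        params = CohortSimParams(n_participants=8000, carrier_prevalence=0.05, seed=seed)
        if shift:
            means = {k: dict(v) for k, v in params.lipid_means.items()}
            means["carrier"]["ldl"] = means["noncarrier"]["ldl"] + 1.02  # +1 noncarrier SD
            params = CohortSimParams(n_participants=8000, carrier_prevalence=0.05,
                                     lipid_means=means, seed=seed)
        cohort, _ = generate_cohort(params)
        carriers = cohort[cohort["carrier"] == 1]
        carrier_set = pd.DataFrame({
            "participant_id": carriers["participant_id"],
            "variant_ids": "LDLR_PV_01", "genes": "LDLR", "classes": "Pathogenic",
            "n_variants": 1, "two_variants": False,
            "exclusion_reason": "none", "analysis_eligible": True,
        })
        return cohort, carrier_set

    def test_shifted_ldl_detected(self):
        cohort, carrier_set = self._frame(seed=40, shift=True)
        table = lipid_or_models(cohort, carrier_set, lipids=("ldl",))
        row = table[table["group"] == "all"].iloc[0]
        assert row["odds_ratio"] > 1 and row["ci_low"] > 1

    def test_null_lipids_or_near_one(self):
        params = CohortSimParams(
            n_participants=8000, carrier_prevalence=0.05,
            lipid_means={"carrier": dict(DEFAULT := {"tc": 4.2, "ldl": 2.3, "hdl": 1.2, "tg": 1.3}),
                         "noncarrier": dict(DEFAULT)},
            lipid_sds={"carrier": {"tc": 1.2, "ldl": 1.0, "hdl": 0.3, "tg": 0.6},
                       "noncarrier": {"tc": 1.2, "ldl": 1.0, "hdl": 0.3, "tg": 0.6}},
            seed=41)
        cohort, _ = generate_cohort(params)
        carriers = cohort[cohort["carrier"] == 1]
        carrier_set = pd.DataFrame({
            "participant_id": carriers["participant_id"],
            "variant_ids": "LDLR_PV_01", "genes": "LDLR", "classes": "Pathogenic",
            "n_variants": 1, "two_variants": False,
            "exclusion_reason": "none", "analysis_eligible": True,
        })
        table = lipid_or_models(cohort, carrier_set)
        sub = table[table["group"] == "all"]
        logor = np.log(sub["odds_ratio"].to_numpy())
        se = (np.log(sub["ci_high"]) - np.log(sub["odds_ratio"])).to_numpy() / 1.96
        assert (np.abs(logor) < 3 * se).all()

    def test_small_group_skipped_with_warning(self):
        cohort, carrier_set = self._frame(seed=42, shift=False)
        carrier_set = carrier_set.iloc[:3]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            table = lipid_or_models(cohort, carrier_set, lipids=("ldl",))
        assert table.empty
        assert any("skipped" in str(w.message) for w in caught)


class TestGroupSummary:
    def test_icd_bucketing(self):
        assert icd10_buckets_of("I21.4;I10") == {"I20-I25", "I10-I15"}
        assert icd10_buckets_of("E78.0") == {"other"}
        assert icd10_buckets_of(float("nan")) == {"missing"}

    def test_fixture_summary_rows(self, study_fixtures, carrier_analysis):
        fx = study_fixtures
        eligible = set(carrier_analysis.loc[carrier_analysis["analysis_eligible"],
                                            "participant_id"])
        excluded = set(carrier_analysis["participant_id"]) - eligible
        part = fx["participants"]
        analysis = part[~part["participant_id"].isin(excluded)]
        table = group_summary(analysis, eligible)
        ihd_row = table[table["row"] == "Principal diagnosis I20-I25"].iloc[0]
        assert ihd_row["carriers_n"] == 60
        assert ihd_row["carriers"].startswith("60 (78.95%)")
        chol = table[table["row"] == "Cholesterol"].iloc[0]
        assert chol["carriers"].startswith("4.61")
        men = table[table["row"] == "Men"].iloc[0]
        assert men["carriers_n"] == 41

    def test_degenerate_single_group_warns(self, study_fixtures):
        part = study_fixtures["participants"].head(50)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            group_summary(part, set())
        assert any("degenerate" in str(w.message) for w in caught)
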