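"""Carrier versus non-carrier statistics.

Categorical contrasts use Fisher's exact test, quantitative ones the
Mann-Whitney U test, and adjusted effects come from maximum-likelihood
logistic regression: odds ratios are exponentiated coefficients with Wald
95% confidence intervals and two-sided Wald p-values.  Two covariate sets
are used for ischemic heart disease (model 1: sex and age; model 2:
additionally BMI, diabetes and smoking), and lipid contrasts adjust for
age, sex and lipid-lowering therapy of any class, with continuous
covariates standardised to z-scores.  The null hypothesis is rejected at
p < 0.05 (strict).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .phenotype import CARRIER_GROUPS, DegenerateGroupError, carrier_group_mask

ALPHA = 0.05

#: ICD-10 circulatory-chapter buckets used in the cohort summary.
ICD10_BUCKETS = (
    ("I10-I15", 10, 15),
    ("I20-I25", 20, 25),
    ("I26-I28", 26, 28),
    ("I30-I32", 30, 32),
    ("I33-I39", 33, 39),
    ("I40-I43", 40, 43),
    ("I44-I49", 44, 49),
    ("I50", 50, 50),
)


class SeparationError(ValueError):
    """Perfect separation: a regressor fully predicts the outcome."""


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    exposure: str
    covariates: tuple[str, ...] = ()
    standardize: tuple[str, ...] = ()  # continuous covariates z-scored before the fit

    def __post_init__(self) -> None:
        if self.exposure in self.covariates:
            raise ValueError(f"exposure {self.exposure!r} duplicated among covariates")


@dataclass(frozen=True)
class AssociationResult:
    outcome: str
    exposure: str
    covariates: tuple[str, ...]
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_cases: int
    n_total: int

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must bracket the estimate")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


# ---------------------------------------------------------------------------
# Exact / rank tests
# ---------------------------------------------------------------------------

def fisher_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Fisher's exact test for a 2x2 table ``[[a, b], [c, d]]``.

    Returns the sample odds ratio ad/bc (``inf``/``0`` sentinels when a
    margin cell is empty), a Haldane-Anscombe companion estimate
    (0.5 added to every cell), and the exact two-sided p-value (the sum of
    hypergeometric probabilities no larger than the observed table's).
    """
    cells = (a, b, c, d)
    if any((not float(x).is_integer()) or x < 0 for x in cells):
        raise ValueError(f"cell counts must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    if (a + b == 0 or c + d == 0) or (a + c == 0 or b + d == 0):
        raise DegenerateGroupError("a margin of the 2x2 table is zero")
    if b * c == 0:
        odds = math.inf if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {"odds_ratio": odds, "odds_ratio_haldane": haldane, "p_two_sided": float(p)}


def mann_whitney(x, y) -> dict:
    """Mann-Whitney U test, two-sided.

    Exact enumeration when both groups have at most eight observations and
    there are no ties, otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DegenerateGroupError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p_two_sided": float(res.pvalue), "method": method}


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    """Raise naming the offending regressor when one column separates y."""
    for col in X.columns:
        if col == "const":
            continue
        v = X[col].to_numpy(dtype=float)
        lo1, hi0 = v[y == 1].min(initial=np.inf), v[y == 0].max(initial=-np.inf)
        lo0, hi1 = v[y == 0].min(initial=np.inf), v[y == 1].max(initial=-np.inf)
        if lo1 > hi0 or lo0 > hi1:
            raise SeparationError(f"perfect separation of the outcome by {col!r}")


def fit_logistic_or(data: pd.DataFrame, spec: ModelSpec, maxiter: int = 100) -> AssociationResult:
    """Maximum-likelihood logistic fit; the exposure OR with Wald 95% CI."""
    cols = [spec.outcome, spec.exposure, *spec.covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"model data missing columns: {missing}")
    frame = data[cols].dropna()
    n_dropped = len(data) - len(frame)
    if n_dropped:
        warnings.warn(f"complete-case analysis dropped {n_dropped} rows with missing values")
    y = frame[spec.outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {spec.outcome!r} must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateGroupError(f"outcome {spec.outcome!r} is constant")
    X = frame[[spec.exposure, *spec.covariates]].astype(float).copy()
    for col in spec.standardize:
        sd = X[col].std(ddof=0)
        if sd == 0:
            raise ValueError(f"covariate {col!r} is constant; cannot standardize")
        X[col] = (X[col] - X[col].mean()) / sd
    X = sm.add_constant(X, has_constant="add")
    _check_separation(X.drop(columns="const"), y)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=maxiter)
    except Exception as e:  # statsmodels PerfectSeparationError et al.
        raise SeparationError(f"logistic fit failed: {e}") from e
    if not fit.mle_retvals.get("converged", False):
        raise RuntimeError(f"logistic fit did not converge within {maxiter} iterations")
    beta = fit.params[spec.exposure]
    se = fit.bse[spec.exposure]
    z = stats.norm.ppf(1 - ALPHA / 2)
    return AssociationResult(
        outcome=spec.outcome,
        exposure=spec.exposure,
        covariates=tuple(spec.covariates),
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=float(fit.pvalues[spec.exposure]),
        n_cases=int(y.sum()),
        n_total=int(len(y)),
    )


def ihd_model_spec(model: int = 1) -> ModelSpec:
    """The two IHD covariate sets: model 1 sex+age, model 2 adds BMI, diabetes, smoking."""
    if model == 1:
        return ModelSpec("ihd", "carrier", ("sex_male", "age"), standardize=("age",))
    if model == 2:
        return ModelSpec(
            "ihd", "carrier", ("sex_male", "age", "bmi", "diabetes", "smoking_dependent"),
            standardize=("age", "bmi"),
        )
    raise ValueError("model must be 1 or 2")


def lipid_or_models(
    data: pd.DataFrame,
    carrier_set: pd.DataFrame,
    lipids: tuple[str, ...] = ("tc", "hdl", "ldl", "tg"),
    min_group_size: int = 5,
) -> pd.DataFrame:
    """Age-, sex- and therapy-adjusted lipid odds ratios per carrier group.

    For each report group, carrier-group membership (vs non-carriers) is
    regressed on each standardised lipid with age (z), sex and any
    lipid-lowering therapy as covariates; the OR is per standard deviation
    of the lipid.  Groups below ``min_group_size`` are skipped with a
    warning.
    """
    carriers_all = set(carrier_set["participant_id"])
    rows = []
    for group in CARRIER_GROUPS:
        members = set(carrier_set.loc[carrier_group_mask(carrier_set, group), "participant_id"])
        if len(members) < min_group_size:
            warnings.warn(f"carrier group {group!r} has n={len(members)} < {min_group_size}; skipped")
            continue
        sub = data[data["participant_id"].isin(members) | ~data["participant_id"].isin(carriers_all)].copy()
        sub["in_group"] = sub["participant_id"].isin(members).astype(int)
        for lipid in lipids:
            spec = ModelSpec(
                "in_group", lipid, ("age", "sex_male", "on_lipid_lowering"),
                standardize=("age",),
            )
            frame = sub.copy()
            sd = frame[lipid].std(ddof=0)
            frame[lipid] = (frame[lipid] - frame[lipid].mean()) / sd
            res = fit_logistic_or(frame, spec)
            rows.append({
                "group": group, "lipid": lipid, "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low, "ci_high": res.ci_high, "p_value": res.p_value,
                "n_group": len(members), "n_total": res.n_total,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort summary (carriers vs non-carriers)
# ---------------------------------------------------------------------------

def icd10_bucket(code) -> str:
    """Bucket a single ICD-10 code into the circulatory chapters used here."""
    if code is None or (isinstance(code, float) and np.isnan(code)) or str(code) == "":
        return "missing"
    s = str(code).strip().upper()
    if s.startswith("I") and len(s) >= 3 and s[1:3].isdigit():
        num = int(s[1:3])
        for label, lo, hi in ICD10_BUCKETS:
            if lo <= num <= hi:
                return label
    return "other"


def icd10_buckets_of(codes) -> set[str]:
    """Bucket labels touched by a semicolon-separated ICD-10 code list.

    Discharge records usually carry several codes, so chapter rows overlap
    and can sum to more than 100%.
    """
    if codes is None or (isinstance(codes, float) and np.isnan(codes)):
        return {"missing"}
    parts = [p for p in str(codes).split(";") if p.strip()]
    if not parts:
        return {"missing"}
    return {icd10_bucket(p) for p in parts}


def _adjusted_p(data: pd.DataFrame, indicator: np.ndarray) -> float:
    """Sex- and age-adjusted p for a binary row indicator, via logistic regression."""
    frame = data[["carrier", "sex_male", "age"]].copy()
    frame["row_ind"] = indicator.astype(float)
    spec = ModelSpec("row_ind", "carrier", ("sex_male", "age"), standardize=("age",))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # near-separated rows fall back to NaN
            return fit_logistic_or(frame, spec).p_value
    except (SeparationError, DegenerateGroupError, ValueError, RuntimeError):
        return float("nan")


def group_summary(participants: pd.DataFrame, carrier_ids: set) -> pd.DataFrame:
    """Carrier vs non-carrier cohort characteristics table.

    Categorical rows report N (%) per group with Fisher's exact p and a
    sex/age-adjusted logistic p; continuous rows report median [Q1; Q3]
    with a Mann-Whitney p.  Principal diagnoses are bucketed into ICD-10
    circulatory-chapter ranges.
    """
    df = participants.copy()
    df["carrier"] = df["participant_id"].isin(carrier_ids).astype(int)
    df["sex_male"] = df["sex"].eq("M").astype(int)
    car = df[df["carrier"] == 1]
    non = df[df["carrier"] == 0]
    if car.empty or non.empty:
        warnings.warn("degenerate split: one of the comparison groups is empty")
    rows = []

    def cat_row(label: str, indicator: pd.Series) -> None:
        ind = indicator.fillna(False).astype(bool).to_numpy()
        a = int(ind[df["carrier"] == 1].sum()); b = len(car) - a
        c = int(ind[df["carrier"] == 0].sum()); d = len(non) - c
        try:
            p = fisher_2x2(a, b, c, d)["p_two_sided"]
        except (DegenerateGroupError, ValueError):
            p = float("nan")
        rows.append({
            "row": label, "kind": "categorical",
            "carriers": f"{a} ({100 * a / len(car):.2f}%)" if len(car) else "0",
            "non_carriers": f"{c} ({100 * c / len(non):.2f}%)" if len(non) else "0",
            "carriers_n": a, "non_carriers_n": c,
            "p_unadjusted": p, "p_adjusted": _adjusted_p(df, ind),
        })

    def cont_row(label: str, col: str) -> None:
        xc = car[col].dropna().to_numpy(dtype=float)
        xn = non[col].dropna().to_numpy(dtype=float)
        try:
            p = mann_whitney(xc, xn)["p_two_sided"]
        except DegenerateGroupError:
            p = float("nan")

        def med(v):
            if len(v) == 0:
                return "NA"
            q1, q2, q3 = np.percentile(v, [25, 50, 75])
            return f"{q2:.3g} [{q1:.3g}; {q3:.3g}]"

        rows.append({
            "row": label, "kind": "continuous",
            "carriers": med(xc), "non_carriers": med(xn),
            "carriers_n": len(xc), "non_carriers_n": len(xn),
            "p_unadjusted": p, "p_adjusted": float("nan"),
        })

    cat_row("Men", df["sex"].eq("M"))
    cat_row("Women", df["sex"].eq("F"))
    cont_row("Age", "age")
    for label, lo, hi in [("Underweight", 0, 18.5), ("Healthy weight", 18.5, 25),
                          ("Overweight (pre-obese)", 25, 30), ("Obesity I", 30, 35),
                          ("Obesity II", 35, 40), ("Obesity III", 40, 200)]:
        cat_row(f"BMI: {label}", (df["bmi"] >= lo) & (df["bmi"] < hi))
    cat_row("Nicotine dependence", df["smoking"].eq("dependent"))
    cat_row("Diabetes mellitus", df["diabetes"].astype(bool))
    buckets = df["icd10_primary"].map(icd10_buckets_of)
    for label, _, _ in ICD10_BUCKETS:
        cat_row(f"Principal diagnosis {label}", buckets.map(lambda s, lab=label: lab in s))
    cat_row("Principal diagnosis other", buckets.map(lambda s: "other" in s))
    for label, col in [("Cholesterol", "tc"), ("LDL", "ldl"), ("HDL", "hdl"),
                       ("Triglycerides", "tg")]:
        cont_row(label, col)
    cat_row("Lipid-lowering therapy", df["on_lipid_lowering"].astype(bool))
    return pd.DataFrame(rows)
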