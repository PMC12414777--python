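"""Synthetic cohorts, annotation tables, and printed-table fixtures.

Three generators back the test strategy:

* :func:`generate_cohort` draws a participant table from a known generative
  model (logistic IHD risk with a carrier effect, per-status lipid
  distributions, invertible treatment deflation of LDL-C) so the
  association stage can be checked by parameter recovery.
* :func:`generate_annotations` emits variant annotation rows that cover
  every branch of the triage decision tree, each tagged with the class the
  engine must output, so triage is checked against generator ground truth.
* :func:`build_table_fixtures` deterministically reconstructs a cohort
  whose marginal counts equal the study's printed tables (76 eligible
  carriers / 4,770 non-carriers, subgroup sizes 37/24/15, penetrance and
  diagnosis counts); individual-level values are synthesised only where a
  count or a median constrains them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .triage import ANNOTATION_COLUMNS, SCORE_FIELDS

#: Seed of the deterministic fixture reconstruction (documented; not a dial).
FIXTURE_SEED = 20250928

DEFAULT_LIPID_MEANS = {
    # observed mmol/L, carriers vs non-carriers (TC, LDL-C, HDL-C, TG)
    "carrier": {"tc": 4.61, "ldl": 2.59, "hdl": 1.21, "tg": 1.19},
    "noncarrier": {"tc": 4.19, "ldl": 2.30, "hdl": 1.17, "tg": 1.32},
}
DEFAULT_LIPID_SDS = {
    "carrier": {"tc": 1.84, "ldl": 1.63, "hdl": 0.36, "tg": 0.67},
    "noncarrier": {"tc": 1.23, "ldl": 1.02, "hdl": 0.32, "tg": 0.62},
}


@dataclass(frozen=True)
class CohortSimParams:
    """Generative settings for a synthetic cardiology cohort.

    Defaults reproduce the study conditions: 4,856 inpatients, carrier
    prevalence 86/4,856, 43% women, a sex- and age-adjusted carrier odds
    ratio for IHD of 1.31, observed lipid levels centred on the printed
    carrier / non-carrier medians, and ~64.5% of participants on
    lipid-lowering therapy whose recorded maximum LDL-C is deflated by the
    (invertible) correction factor of their regimen.  The extra model-2
    covariates (BMI, diabetes, smoking) default to null effects so the
    sex/age model is correctly specified.
    """

    n_participants: int = 4856
    carrier_prevalence: float = 86 / 4856
    female_fraction: float = 0.43
    age_mean: float = 65.0
    age_sd: float = 11.0
    baseline_ihd_logit: float = 0.0
    true_carrier_or: float = 1.31
    sex_male_logor: float = 0.3
    age_logor_per_sd: float = 0.3
    bmi_logor_per_sd: float = 0.0
    diabetes_logor: float = 0.0
    smoking_logor: float = 0.0
    diabetes_prevalence: float = 0.22
    smoking_prevalence: float = 0.135
    lipid_means: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LIPID_MEANS.items()})
    lipid_sds: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LIPID_SDS.items()})
    treated_fraction: float = 0.645
    treatment_factor: float = 1.61  # moderate-intensity statin in the shipped table
    seed: int = 0

    def validate(self) -> None:
        for name in ("carrier_prevalence", "female_fraction", "treated_fraction",
                     "diabetes_prevalence", "smoking_prevalence"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if not (np.isfinite(self.true_carrier_or) and self.true_carrier_or > 0):
            raise ValueError(f"true_carrier_or must be positive, got {self.true_carrier_or}")
        if self.n_participants <= 0:
            raise ValueError(f"n_participants must be positive, got {self.n_participants}")
        if not np.isfinite(self.age_mean) or self.age_sd <= 0:
            raise ValueError(f"age_mean/age_sd invalid: {self.age_mean}/{self.age_sd}")
        if self.treatment_factor < 1:
            raise ValueError(f"treatment_factor must be >= 1, got {self.treatment_factor}")
        for status in ("carrier", "noncarrier"):
            for lipid, sd in self.lipid_sds[status].items():
                if sd <= 0:
                    raise ValueError(f"lipid_sds[{status}][{lipid}] must be > 0, got {sd}")


def generate_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, dict]:
    """Draw a participant table plus the ground truth that produced it.

    IHD is Bernoulli under a logistic model with carrier log-odds
    ``ln(true_carrier_or)`` plus sex and standardised-age terms (and
    optional BMI/diabetes/smoking terms); ages are truncated-normal on
    [18, 100]; lipids are drawn per carrier status; treated participants'
    observed maximum LDL-C equals the true value divided by the treatment
    factor, so pre-treatment back-correction is exactly invertible.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_participants

    carrier = rng.random(n) < params.carrier_prevalence
    female = rng.random(n) < params.female_fraction
    a, b = (18 - params.age_mean) / params.age_sd, (100 - params.age_mean) / params.age_sd
    age = stats.truncnorm.rvs(a, b, loc=params.age_mean, scale=params.age_sd,
                              size=n, random_state=rng)
    z_age = (age - params.age_mean) / params.age_sd
    bmi = np.clip(rng.normal(27.5, 4.8, size=n), 15, 60)
    z_bmi = (bmi - 27.5) / 4.8
    diabetes = rng.random(n) < params.diabetes_prevalence
    smoking = rng.random(n) < params.smoking_prevalence

    logit = (
        params.baseline_ihd_logit
        + math.log(params.true_carrier_or) * carrier
        + params.sex_male_logor * (~female)
        + params.age_logor_per_sd * z_age
        + params.bmi_logor_per_sd * z_bmi
        + params.diabetes_logor * diabetes
        + params.smoking_logor * smoking
    )
    ihd = rng.random(n) < expit(logit)

    lipids = {}
    for lipid in ("tc", "ldl", "hdl", "tg"):
        vals = np.where(
            carrier,
            rng.normal(params.lipid_means["carrier"][lipid],
                       params.lipid_sds["carrier"][lipid], size=n),
            rng.normal(params.lipid_means["noncarrier"][lipid],
                       params.lipid_sds["noncarrier"][lipid], size=n),
        )
        lipids[lipid] = np.clip(vals, 0.1, None)

    max_ldl_true = lipids["ldl"] + np.abs(rng.normal(0.4, 0.3, size=n))
    treated = rng.random(n) < params.treated_fraction
    max_ldl_observed = np.where(treated, max_ldl_true / params.treatment_factor, max_ldl_true)

    df = pd.DataFrame({
        "participant_id": [f"S{i:06d}" for i in range(n)],
        "sex": np.where(female, "F", "M"),
        "age": age,
        "bmi": bmi,
        "smoking": np.where(smoking, "dependent", "never_former"),
        "diabetes": diabetes,
        "alcohol_audit_c": rng.integers(0, 7, size=n),
        "icd10_primary": np.where(ihd, "I25.1", "I10"),
        "tc": lipids["tc"], "ldl": lipids["ldl"], "hdl": lipids["hdl"], "tg": lipids["tg"],
        "max_ldl_observed": max_ldl_observed,
        "on_lipid_lowering": treated,
        "therapy_class": np.where(treated, "statin", "none"),
        "therapy_intensity": np.where(treated, "moderate", "none"),
        "prior_fh_diagnosis": False,
        "carrier": carrier.astype(int),
        "ihd": ihd.astype(int),
        "sex_male": (~female).astype(int),
        "smoking_dependent": smoking.astype(int),
    })
    truth = {
        "true_carrier_or": params.true_carrier_or,
        "true_carrier_logor": math.log(params.true_carrier_or),
        "max_ldl_true": max_ldl_true,
        "treatment_factor": params.treatment_factor,
        "params": params,
    }
    return df, truth


# ---------------------------------------------------------------------------
# Annotation generator: one archetype per triage branch outcome
# ---------------------------------------------------------------------------

_DEL = {  # score draws that vote deleterious
    "SIFT": (0.0, 0.049), "PolyPhen2_HDIV": (0.951, 1.0), "MutationAssessor": (2.0, 5.0),
    "M_CAP": (0.03, 0.6), "CADD": (15.0, 40.0), "REVEL": (0.76, 1.0),
    "MetaLR": (0.51, 1.0), "MetaSVM": (0.1, 1.5),
}
_BEN = {  # score draws that vote benign
    "SIFT": (0.2, 1.0), "PolyPhen2_HDIV": (0.0, 0.5), "MutationAssessor": (-2.0, 1.5),
    "M_CAP": (0.0, 0.02), "CADD": (0.0, 10.0), "REVEL": (0.0, 0.5),
    "MetaLR": (0.0, 0.45), "MetaSVM": (-1.5, -0.1),
}

#: Each archetype pins the triage inputs that decide a branch and tags the
#: class the engine must output.  "del"/"ben" mark score strata; None = the
#: score is missing.  MAF "rare" draws below the candidate threshold,
#: "absent" is unreported, "common" fails the MAF filter.
BRANCH_ARCHETYPES: dict[str, dict] = {
    "A_pathogenic": dict(gene="LDLR", consequence="nonsense", clinvar="P",
                         review="multiple_submitters", intervar="LP", scores="del",
                         maf="rare", truth="Pathogenic", branch="A"),
    "A_likely": dict(gene="APOB", consequence="missense", clinvar="LP",
                     review="expert_panel", intervar="P", scores="del",
                     maf="absent", truth="LikelyPathogenic", branch="A"),
    "B_consensus": dict(gene="LDLR", consequence="missense", clinvar="P",
                        review="multiple_submitters", intervar="VUS", scores="del",
                        maf="rare", truth="LikelyPathogenic", branch="B"),
    "B_fail": dict(gene="LDLR", consequence="missense", clinvar="LP",
                   review="multiple_submitters", intervar="VUS", scores="ben",
                   maf="rare", truth="VUS", branch="B"),
    "B_tiebreak": dict(gene="LDLR", consequence="missense", clinvar="P",
                       review="multiple_submitters", intervar="VUS",
                       scores={"SIFT": "del", "PolyPhen2_HDIV": "del", "MutationAssessor": None,
                               "M_CAP": None, "CADD": None, "REVEL": "del",
                               "MetaLR": "del", "MetaSVM": "del"},
                       maf="absent", truth="LikelyPathogenic", branch="B"),
    "C_confirmed": dict(gene="LDLR", consequence="frameshift", clinvar="P",
                        review="single_submitter", intervar="LP", scores="del",
                        maf="rare", clinical=True, truth="Pathogenic", branch="C"),
    "C_downgraded": dict(gene="LDLR", consequence="missense", clinvar="P",
                         review="criteria_not_provided", intervar="LB", scores="ben",
                         maf="rare", truth="VUS", branch="C"),
    "D_review": dict(gene="APOB", consequence="missense", clinvar="LP",
                     review="single_submitter", intervar="LP", scores="del",
                     maf="rare", truth="LikelyPathogenic", branch="D"),
    "E_expert": dict(gene="LDLR", consequence="splice", clinvar="VUS",
                     review="expert_panel", intervar="LP", scores="del",
                     region="splice_site", maf="rare",
                     truth="LikelyPathogenic", branch="E"),
    "E_review": dict(gene="PCSK9", consequence="missense", clinvar="not_reported",
                     review="none", intervar="P", scores="del", maf="absent",
                     truth="LikelyPathogenic", branch="E"),
    "E_vus": dict(gene="APOB", consequence="missense", clinvar="VUS",
                  review="single_submitter", intervar="VUS", scores="ben",
                  maf="rare", truth="VUS", branch="E"),
    "F_deleterious": dict(gene="LDLR", consequence="missense", clinvar="not_reported",
                          review="none", intervar="VUS",
                          scores={"SIFT": "ben", "PolyPhen2_HDIV": "ben", "MutationAssessor": "ben",
                                  "M_CAP": "ben", "CADD": "ben", "REVEL": None,
                                  "MetaLR": "del", "MetaSVM": "del"},
                          maf="absent", truth="VUS_deleterious", branch="F"),
    "F_plain": dict(gene="LDLR", consequence="missense", clinvar="VUS",
                    review="single_submitter", intervar="VUS", scores="ben",
                    maf="rare", truth="VUS", branch="F"),
    "X_maf": dict(gene="LDLR", consequence="missense", clinvar="VUS",
                  review="single_submitter", intervar="VUS", scores="ben",
                  maf="common", truth="Excluded", branch="filter", reason="maf"),
    "X_benign": dict(gene="APOB", consequence="synonymous", clinvar="LB",
                     review="multiple_submitters", intervar="LB", scores="ben",
                     maf="rare", truth="Excluded", branch="filter", reason="benign_in_clinvar"),
    "X_region": dict(gene="LDLR", consequence="other", clinvar="not_reported",
                     review="none", intervar="not_available", scores="ben",
                     region="other", maf="rare", truth="Excluded", branch="filter",
                     reason="region"),
    "X_gene": dict(gene="APOE", consequence="missense", clinvar="VUS",
                   review="single_submitter", intervar="VUS", scores="ben",
                   maf="rare", truth="Excluded", branch="filter", reason="gene"),
}


@dataclass(frozen=True)
class AnnotationSimParams:
    """Settings for the branch-covering annotation generator."""

    n_variants: int = 180
    branch_mix: dict = field(
        default_factory=lambda: {k: 1 / len(BRANCH_ARCHETYPES) for k in BRANCH_ARCHETYPES}
    )
    maf_rare_range: tuple[float, float] = (1e-7, 9e-5)
    maf_common_range: tuple[float, float] = (2e-4, 1e-2)
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 0:
            raise ValueError(f"n_variants must be non-negative, got {self.n_variants}")
        unknown = set(self.branch_mix) - set(BRANCH_ARCHETYPES)
        if unknown:
            raise ValueError(f"branch_mix names unknown archetypes: {sorted(unknown)}")
        total = sum(self.branch_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(f"branch_mix must sum to 1, got {total}")
        if any(w < 0 for w in self.branch_mix.values()):
            raise ValueError("branch_mix weights must be non-negative")


_GENE_CHROM_POS = {"LDLR": ("19", 11_089_000), "APOB": ("2", 21_000_000),
                   "PCSK9": ("1", 55_039_000), "APOE": ("19", 44_905_000)}


def _draw_scores(rng: np.random.Generator, spec) -> dict:
    if isinstance(spec, str):
        spec = {name: spec for name in SCORE_FIELDS}
    out = {}
    for name in SCORE_FIELDS:
        stratum = spec.get(name)
        if stratum is None:
            out[name] = np.nan
        else:
            lo, hi = (_DEL if stratum == "del" else _BEN)[name]
            out[name] = rng.uniform(lo, hi)
    return out


def generate_annotations(params: AnnotationSimParams) -> pd.DataFrame:
    """Annotation rows tagged with the class the triage engine must output.

    Every archetype with positive weight contributes at least one row (the
    default mix covers all branches A-F plus each exclusion reason), then
    the remainder is sampled from ``branch_mix``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    names = [k for k, w in params.branch_mix.items() if w > 0]
    picks = list(names[: params.n_variants])
    if params.n_variants > len(picks):
        weights = np.array([params.branch_mix[k] for k in names])
        weights = weights / weights.sum()
        picks += list(rng.choice(names, size=params.n_variants - len(picks), p=weights))

    rows = []
    for i, name in enumerate(picks):
        arch = BRANCH_ARCHETYPES[name]
        gene = arch["gene"]
        chrom, base = _GENE_CHROM_POS[gene]
        pos = base + 7 * i + int(rng.integers(0, 5))
        maf_kind = arch["maf"]
        if maf_kind == "absent":
            maf = np.nan
        elif maf_kind == "rare":
            maf = rng.uniform(*params.maf_rare_range)
        else:
            maf = rng.uniform(*params.maf_common_range)
        row = {
            "variant_id": f"{chrom}:{pos}:A:G",
            "gene": gene,
            "region": arch.get("region", "exonic"),
            "variant_type": "SNV",
            "consequence": arch["consequence"],
            "gnomad_maf": maf,
            "clinvar_class": arch["clinvar"],
            "clinvar_review": arch["review"],
            "intervar_class": arch["intervar"],
            "clinical_case_support": arch.get("clinical", False),
            **_draw_scores(rng, arch["scores"]),
            "truth_class": arch["truth"],
            "truth_branch": arch["branch"],
            "truth_exclusion_reason": arch.get("reason"),
            "archetype": name,
        }
        rows.append(row)
    cols = list(ANNOTATION_COLUMNS) + ["truth_class", "truth_branch",
                                       "truth_exclusion_reason", "archetype"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Printed-table fixture reconstruction
# ---------------------------------------------------------------------------

def _quantile_anchored(n: int, lo: float, q1: float, med: float, q3: float,
                       hi: float) -> np.ndarray:
    """Sorted values of length n whose 25/50/75 percentiles are exact.

    Percentile anchor indices are pinned to the quantile value; the rest is
    linear interpolation between anchors.
    """
    if not lo <= q1 <= med <= q3 <= hi:
        raise ValueError("quantile anchors must be non-decreasing")
    xs, ys = [0.0], [lo]
    for p, v in ((0.25, q1), (0.5, med), (0.75, q3)):
        pos = p * (n - 1)
        for i in (math.floor(pos), math.ceil(pos)):
            if i > xs[-1]:
                xs.append(float(i)); ys.append(v)
            elif i == xs[-1]:
                ys[-1] = v
    if xs[-1] < n - 1:
        xs.append(float(n - 1)); ys.append(hi)
    return np.interp(np.arange(n, dtype=float), xs, ys)


def _spread_counts(n: int, counts: dict[str, int],
                   rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
    """Boolean masks with exact counts; independently permuted when given a rng
    so unconstrained traits do not align into spurious joint structure."""
    masks = {}
    for name, k in counts.items():
        m = np.zeros(n, dtype=bool)
        m[:k] = True
        if rng is not None:
            m = m[rng.permutation(n)]
        masks[name] = m
    return masks


# Carrier-side printed constraints (eligible carriers, by subgroup):
#   subgroup sizes 37 (LDLR PV/LP), 24 (LDLR VUS-deleterious), 15 (APOB)
#   prior FH 8/0/0; post-hoc FH criteria 6/0/6; IHD history 30/18/13
#   corrected max LDL >=4.0: 29/12/14; >=4.9: 24/4/12
_SUBGROUPS = (("LDLR_PVLP", 37), ("LDLR_VUS_deleterious", 24), ("APOB", 15))
_SG_CONSTRAINTS = {
    "LDLR_PVLP": dict(prior_fh=8, posthoc_fh=6, ihd=30, ldl_ge_49=24, ldl_40_49=5),
    "LDLR_VUS_deleterious": dict(prior_fh=0, posthoc_fh=0, ihd=18, ldl_ge_49=4, ldl_40_49=8),
    "APOB": dict(prior_fh=0, posthoc_fh=6, ihd=13, ldl_ge_49=12, ldl_40_49=2),
}

#: Carrier counts from the cohort characteristics table (n = 76).
_CARRIER_T1 = dict(
    men=41, smoking_dependent=8, diabetes=17, audit_zero=43, audit_positive=11,
    on_lipid_lowering=52,
    icd={"I10-I15": 54, "I20-I25": 60, "I26-I28": 3, "I30-I32": 0, "I33-I39": 10,
         "I40-I43": 1, "I44-I49": 26, "I50": 1, "other": 2},
    bmi_categories=(0, 20, 36, 15, 5, 0),
    lipids={"tc": (3.70, 4.61, 6.18), "ldl": (1.775, 2.59, 3.975),
            "hdl": (0.9375, 1.205, 1.43), "tg": (0.8775, 1.19, 1.785)},
)

#: Non-carrier counts (n = 4,770).
_NONCARRIER_T1 = dict(
    men=2721, smoking_dependent=655, diabetes=1049, audit_zero=2693, audit_positive=754,
    on_lipid_lowering=3063,
    icd={"I10-I15": 3492, "I20-I25": 2551, "I26-I28": 232, "I30-I32": 11, "I33-I39": 278,
         "I40-I43": 177, "I44-I49": 2484, "I50": 116, "other": 258},
    bmi_categories=(38, 1058, 1852, 1245, 421, 155),
    lipids={"tc": (3.48, 4.19, 5.14), "ldl": (1.73, 2.30, 3.11),
            "hdl": (0.98, 1.17, 1.41), "tg": (0.98, 1.32, 1.81)},
)

_BUCKET_CODE = {"I10-I15": "I10", "I20-I25": "I25.1", "I26-I28": "I26", "I30-I32": "I30",
                "I33-I39": "I34", "I40-I43": "I42", "I44-I49": "I48", "I50": "I50",
                "other": "E78.0"}
_BMI_CATEGORY_VALUES = (17.5, 22.0, 27.0, 32.0, 37.0, 42.0)

#: Per-subgroup corrected-max-LDL levels for the three penetrance bands.
#: FH-criteria carriers get the 6.8 level (DLCN LDL band 6.5-8.4 = 5 points).
_LDL_BAND_VALUES = {"ge49": 5.6, "fh": 6.8, "mid": 4.3, "low": 3.2}

#: Statin correction factor used when a fixture carrier is on therapy.
_FIXTURE_THERAPY = ("statin", "moderate", 1.61)


def _build_variants() -> pd.DataFrame:
    """44 synthetic panel variants mirroring the printed class structure."""
    rows = []
    for i in range(27):
        cls = "Pathogenic" if i % 2 == 0 else "LikelyPathogenic"
        rows.append(("LDLR_PV_%02d" % (i + 1), "LDLR", cls, "A"))
    for i in range(15):
        rows.append(("LDLR_VD_%02d" % (i + 1), "LDLR", "VUS_deleterious", "F"))
    rows.append(("APOB_R3527Q", "APOB", "Pathogenic", "A"))
    rows.append(("APOB_Q4494DEL", "APOB", "LikelyPathogenic", "B"))
    df = pd.DataFrame(rows, columns=["variant_id", "gene", "final_class", "fired_branch"])
    df["exclusion_reason"] = None
    df["evidence_summary"] = "synthetic fixture variant"
    df["chrom"] = df["gene"].map({"LDLR": "19", "APOB": "2"})
    df["pos"] = [_GENE_CHROM_POS[g][1] + 150 * i for i, g in enumerate(df["gene"])]
    df["ref"] = "G"
    df["alt"] = "A"
    return df


def build_table_fixtures(outdir: str | Path | None = None,
                         write_full_cohort: bool = True) -> dict[str, pd.DataFrame]:
    """Reconstruct the study cohort's printed marginals as analysis inputs.

    Returns ``participants`` (4,856 rows), ``genotypes``, ``variants``,
    ``carriers`` (86 rows of carrier metadata incl. the cascade-relative
    flags) and ``constrained_cells`` (which printed numbers pin which
    columns).  Writing to ``outdir`` also emits a README and manifest.
    Fully deterministic: repeated calls are identical.
    """
    rng = np.random.default_rng(FIXTURE_SEED)
    variants = _build_variants()

    # ---- eligible carriers (76) --------------------------------------
    sg_names = np.concatenate([[name] * size for name, size in _SUBGROUPS])
    n_car = len(sg_names)  # 76
    car = pd.DataFrame({"participant_id": [f"FH{i + 1:04d}" for i in range(n_car)],
                        "subgroup": sg_names})
    prior = np.zeros(n_car, bool)
    posthoc = np.zeros(n_car, bool)
    ihd = np.zeros(n_car, bool)
    ldl_level = np.empty(n_car)
    offset = 0
    for name, size in _SUBGROUPS:
        c = _SG_CONSTRAINTS[name]
        sl = np.arange(offset, offset + size)
        prior[sl[:c["prior_fh"]]] = True
        # post-hoc FH carriers sit inside the >=4.9 band, after the prior-diagnosed
        posthoc[sl[c["prior_fh"]:c["prior_fh"] + c["posthoc_fh"]]] = True
        ihd[sl[:c["ihd"]]] = True
        lv = np.full(size, _LDL_BAND_VALUES["low"])
        lv[:c["ldl_ge_49"]] = _LDL_BAND_VALUES["ge49"]
        lv[c["prior_fh"]:c["prior_fh"] + c["posthoc_fh"]] = _LDL_BAND_VALUES["fh"]
        lv[c["ldl_ge_49"]:c["ldl_ge_49"] + c["ldl_40_49"]] = _LDL_BAND_VALUES["mid"]
        ldl_level[sl] = lv
        offset += size
    car["prior_fh_diagnosis"] = prior
    car["fh_criteria_expected"] = posthoc
    car["ihd"] = ihd
    car["corrected_max_ldl_target"] = ldl_level

    t1 = _CARRIER_T1
    perm = rng.permutation(n_car)
    sex = np.full(n_car, "F", dtype=object)
    sex[perm[:t1["men"]]] = "M"
    car["sex"] = sex
    masks = _spread_counts(n_car, {"smoking": t1["smoking_dependent"],
                                   "diabetes": t1["diabetes"],
                                   "treated": t1["on_lipid_lowering"]}, rng=rng)
    car["smoking"] = np.where(masks["smoking"], "dependent", "never_former")
    car["diabetes"] = masks["diabetes"]
    treated = masks["treated"]
    audit = np.ones(n_car, dtype=int)
    audit[:t1["audit_zero"]] = 0
    audit[t1["audit_zero"]:t1["audit_zero"] + t1["audit_positive"]] = 4
    car["alcohol_audit_c"] = audit[rng.permutation(n_car)]

    # diagnosis code lists: IHD-history carriers hold the I20-I25 codes first
    icd_counts = dict(t1["icd"])
    code_lists = [[] for _ in range(n_car)]
    ihd_idx = np.flatnonzero(ihd)
    for i in ihd_idx[:icd_counts.pop("I20-I25")]:
        code_lists[i].append(_BUCKET_CODE["I20-I25"])
    for name, m in _spread_counts(n_car, icd_counts, rng=rng).items():
        for i in np.flatnonzero(m):
            code_lists[i].append(_BUCKET_CODE[name])

    drug, intensity, factor = _FIXTURE_THERAPY
    car["on_lipid_lowering"] = treated
    car["therapy_class"] = np.where(treated, drug, "none")
    car["therapy_intensity"] = np.where(treated, intensity, "none")
    car["max_ldl_observed"] = np.where(treated, ldl_level / factor, ldl_level)

    lipid_cols = {}
    for lipid, (q1, med, q3) in t1["lipids"].items():
        lo = max(0.1, q1 - 1.2 * (q3 - q1))
        hi = q3 + 1.5 * (q3 - q1)
        vals = _quantile_anchored(n_car, lo, q1, med, q3, hi)
        lipid_cols[lipid] = vals[np.argsort(rng.permutation(n_car), kind="stable")]
    for lipid, vals in lipid_cols.items():
        car[lipid] = vals
    bmi_vals = np.concatenate([
        np.full(k, v) for k, v in zip(t1["bmi_categories"], _BMI_CATEGORY_VALUES)
    ])
    car["bmi"] = bmi_vals[rng.permutation(n_car)]
    car["age"] = _quantile_anchored(n_car, 40, 56, 65, 73, 90)[rng.permutation(n_car)]
    car["age_ihd_diagnosis"] = np.where(ihd, np.round(car["age"] - 7), np.nan)
    car["premature_cad"] = posthoc  # drives the clinical-history DLCN points
    car["icd10_primary"] = [";".join(c) for c in code_lists]
    car["cascade_relative"] = False
    car["analysis_role"] = "eligible"
    # PV/LPV screening denominator of 51: the printed subgroup heads give
    # 37 + 15 = 52, so the last APOB carrier (unconstrained row) is left out
    # of the screening group; documented as a reconciliation, not study fact
    pvlp_group = car["subgroup"].isin(["LDLR_PVLP", "APOB"]).to_numpy()
    pvlp_group[n_car - 1] = False
    car["pv_lpv_group"] = pvlp_group

    # ---- excluded carriers (10): 4 two-variant, 2 cascade, 4 Q4494del -
    excl_rows = []
    for j in range(10):
        pid = f"FH{77 + j:04d}"
        if j < 4:
            role = "two_variants"
        elif j < 6:
            role = "cascade_proband_relative"
        else:
            role = "q4494del_carrier"
        excl_rows.append({
            "participant_id": pid, "subgroup": "excluded", "prior_fh_diagnosis": j < 2,
            "fh_criteria_expected": False, "ihd": j % 2 == 0,
            "corrected_max_ldl_target": 3.2 if role == "q4494del_carrier" else 5.0,
            "sex": "M" if j % 2 == 0 else "F", "smoking": "never_former",
            "diabetes": False, "alcohol_audit_c": 0,
            "on_lipid_lowering": role == "two_variants",
            "therapy_class": drug if role == "two_variants" else "none",
            "therapy_intensity": intensity if role == "two_variants" else "none",
            "max_ldl_observed": (5.0 / factor) if role == "two_variants"
            else (3.2 if role == "q4494del_carrier" else 5.0),
            "tc": 5.0, "ldl": 3.0, "hdl": 1.2, "tg": 1.3, "bmi": 27.0,
            "age": 55.0 + j, "age_ihd_diagnosis": np.nan, "premature_cad": False,
            "icd10_primary": "I25.1" if j % 2 == 0 else "I10",
            "cascade_relative": role == "cascade_proband_relative",
            "analysis_role": role,
            "pv_lpv_group": False,
        })
    carriers = pd.concat([car, pd.DataFrame(excl_rows)], ignore_index=True)

    # ---- genotypes ----------------------------------------------------
    pv_ids = variants.loc[variants["final_class"].isin(["Pathogenic", "LikelyPathogenic"])
                          & (variants["gene"] == "LDLR"), "variant_id"].tolist()
    vd_ids = variants.loc[variants["final_class"] == "VUS_deleterious", "variant_id"].tolist()
    geno_rows = []
    sub = carriers["subgroup"].to_numpy()
    role = carriers["analysis_role"].to_numpy()
    counters = {"pv": 0, "vd": 0}
    for i, pid in enumerate(carriers["participant_id"]):
        if sub[i] == "LDLR_PVLP" or role[i] == "cascade_proband_relative":
            vids = [pv_ids[counters["pv"] % len(pv_ids)]]
            counters["pv"] += 1
        elif sub[i] == "LDLR_VUS_deleterious":
            vids = [vd_ids[counters["vd"] % len(vd_ids)]]
            counters["vd"] += 1
        elif sub[i] == "APOB":
            vids = ["APOB_R3527Q"]
        elif role[i] == "two_variants":
            vids = [pv_ids[counters["pv"] % len(pv_ids)],
                    pv_ids[(counters["pv"] + 1) % len(pv_ids)]]
            counters["pv"] += 2
        else:  # q4494del carriers
            vids = ["APOB_Q4494DEL"]
        for v in vids:
            geno_rows.append({"participant_id": pid, "variant_id": v, "n_alt": 1})
    genotypes = pd.DataFrame(geno_rows)

    # ---- non-carriers (4,770) ----------------------------------------
    t0 = _NONCARRIER_T1
    n_non = 4770
    non = pd.DataFrame({"participant_id": [f"NC{i + 1:04d}" for i in range(n_non)]})
    sex = np.full(n_non, "F", dtype=object)
    sex[rng.permutation(n_non)[:t0["men"]]] = "M"
    non["sex"] = sex
    masks = _spread_counts(n_non, {"smoking": t0["smoking_dependent"],
                                   "diabetes": t0["diabetes"],
                                   "treated": t0["on_lipid_lowering"]}, rng=rng)
    non["smoking"] = np.where(masks["smoking"], "dependent", "never_former")
    non["diabetes"] = masks["diabetes"]
    treated = masks["treated"]
    audit = np.ones(n_non, dtype=int)
    audit[:t0["audit_zero"]] = 0
    audit[t0["audit_zero"]:t0["audit_zero"] + t0["audit_positive"]] = 4
    non["alcohol_audit_c"] = audit[rng.permutation(n_non)]
    code_lists = [[] for _ in range(n_non)]
    icd_counts = dict(t0["icd"])
    ihd_mask = _spread_counts(n_non, {"ihd": icd_counts["I20-I25"]}, rng=rng)["ihd"]
    for i in np.flatnonzero(ihd_mask):
        code_lists[i].append(_BUCKET_CODE["I20-I25"])
    icd_counts.pop("I20-I25")
    for name, m in _spread_counts(n_non, icd_counts, rng=rng).items():
        for i in np.flatnonzero(m):
            code_lists[i].append(_BUCKET_CODE[name])
    non["icd10_primary"] = [";".join(c) for c in code_lists]
    non["ihd"] = ihd_mask
    for lipid, (q1, med, q3) in t0["lipids"].items():
        lo = max(0.1, q1 - 1.2 * (q3 - q1))
        hi = q3 + 1.5 * (q3 - q1)
        non[lipid] = _quantile_anchored(n_non, lo, q1, med, q3, hi)[rng.permutation(n_non)]
    bmi_vals = np.concatenate([
        np.full(k, v) for k, v in zip(t0["bmi_categories"], _BMI_CATEGORY_VALUES)
    ] + [[np.nan]])
    non["bmi"] = bmi_vals[rng.permutation(n_non)]
    non["age"] = _quantile_anchored(n_non, 30, 58, 66, 74, 95)[rng.permutation(n_non)]
    non["age_ihd_diagnosis"] = np.nan
    non["on_lipid_lowering"] = treated
    non["therapy_class"] = np.where(treated, drug, "none")
    non["therapy_intensity"] = np.where(treated, intensity, "none")
    non["max_ldl_observed"] = non["ldl"] + 0.5
    non["prior_fh_diagnosis"] = False
    non["premature_cad"] = False

    part_cols = ["participant_id", "sex", "age", "bmi", "smoking", "diabetes",
                 "alcohol_audit_c", "icd10_primary", "tc", "ldl", "hdl", "tg",
                 "max_ldl_observed", "on_lipid_lowering", "therapy_class",
                 "therapy_intensity", "prior_fh_diagnosis", "ihd",
                 "age_ihd_diagnosis", "premature_cad"]
    participants = pd.concat([carriers[part_cols], non[part_cols]], ignore_index=True)

    constrained = pd.DataFrame([
        {"cell": "eligible carriers", "value": 76},
        {"cell": "non-carriers", "value": 4770},
        {"cell": "total participants", "value": 4856},
        {"cell": "carriers incl. excluded", "value": 86},
        {"cell": "subgroup LDLR", "value": 61},
        {"cell": "subgroup LDLR PV/LP", "value": 37},
        {"cell": "subgroup LDLR VUS-deleterious", "value": 24},
        {"cell": "subgroup APOB", "value": 15},
        {"cell": "carriers corrected max LDL >= 4.0", "value": 55},
        {"cell": "carriers corrected max LDL >= 4.9", "value": 40},
        {"cell": "carriers with prior FH diagnosis", "value": 8},
        {"cell": "carriers meeting FH criteria post hoc", "value": 12},
        {"cell": "carriers with IHD history", "value": 61},
        {"cell": "carriers with I20-I25 code", "value": 60},
    ])

    out = {"participants": participants, "carriers": carriers, "variants": variants,
           "genotypes": genotypes, "constrained_cells": constrained}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = ["carriers.csv", "variants.tsv", "genotypes.tsv", "constrained_cells.csv"]
        if write_full_cohort:
            participants.to_csv(outdir / "participants.csv",
                                index=False, float_format="%.6g")
            written.insert(0, "participants.csv")
        carriers.to_csv(outdir / "carriers.csv", index=False, float_format="%.6g")
        variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
        genotypes.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
        constrained.to_csv(outdir / "constrained_cells.csv", index=False)
        manifest = {
            "seed": FIXTURE_SEED,
            "files": written,
            "n_participants": int(len(participants)),
            "n_carriers": int(len(carriers)),
            "n_eligible": 76,
            "regenerate": "fh-triage simulate --what fixtures --out <dir>  "
                          "(or fh_triage.build_table_fixtures(outdir))",
        }
        import json as _json
        (outdir / "manifest.json").write_text(_json.dumps(manifest, indent=2) + "\n")
        (outdir / "README.md").write_text(_FIXTURE_README)
    return out


_FIXTURE_README = """\
# Study-table fixtures

Deterministic reconstruction (seed 20250928) of the study cohort's printed
marginals.  Only the cells listed in `constrained_cells.csv` are pinned by
printed counts or medians; every other individual-level value is synthetic
filler drawn with the fixed seed and carries no information.

Constrained structure:

* 4,856 participants = 86 carriers + 4,770 non-carriers (prevalence 1.77%).
* 86 carriers = 76 analysis-eligible + 4 two-variant + 2 cascade-screened
  relatives + 4 APOB p.Gln4494del.  The printed exclusion categories sum to
  9 while 86 - 76 = 10; treating cascade relatives as 2 is this fixture's
  documented reconciliation, not study fact.
* Eligible subgroups: 37 LDLR PV/LP + 24 LDLR VUS-deleterious + 15 APOB.
* Corrected maximum LDL-C: 55 carriers >= 4.0 mmol/L (29/12/14 by
  subgroup), 40 >= 4.9 (24/4/12).  Carriers on therapy store deflated
  observed values; multiplying by the statin factor recovers the target.
* FH diagnoses: 8 prior (all LDLR PV/LP); 12 further carriers meet the
  clinical DLCN criteria (6 LDLR PV/LP, 6 APOB).  The `pv_lpv_group`
  column marks the 51-carrier screening denominator: the subgroup heads
  give 37 + 15 = 52, so the last (unconstrained) APOB carrier is left out
  — an assumption documented here.
* Carrier vs non-carrier summary marginals (sex, BMI classes, smoking,
  AUDIT-C, diagnosis-chapter counts incl. 60/76 and 2551/4770 with an
  I20-I25 code, therapy counts) and lipid quartiles (e.g. carrier total
  cholesterol 4.61 [3.70; 6.18] mmol/L) match the printed table exactly.

`participants.csv` (the full 4,856-row cohort) is large and therefore not
committed; regenerate everything with
`fh-triage simulate --what fixtures --out <dir>`.
"""


def build_fixture_annotations(variants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Annotation rows whose triage classification equals the fixture classes.

    Pathogenic/LikelyPathogenic fixture variants are given concordant
    ClinVar + InterVar assertions with strong review (branch A);
    VUS-deleterious ones are unreported rare LDLR missense with MetaLR and
    MetaSVM past their deleterious cutoffs (branch F).
    """
    if variants is None:
        variants = _build_variants()
    rows = []
    for _, v in variants.iterrows():
        base = dict(variant_id=v["variant_id"], gene=v["gene"], region="exonic",
                    variant_type="SNV", consequence="missense", gnomad_maf=np.nan,
                    clinical_case_support=False,
                    **{f: np.nan for f in SCORE_FIELDS})
        if v["final_class"] in ("Pathogenic", "LikelyPathogenic"):
            short = "P" if v["final_class"] == "Pathogenic" else "LP"
            base.update(clinvar_class=short, clinvar_review="multiple_submitters",
                        intervar_class=short)
            if v["gene"] == "LDLR" and "PV" in v["variant_id"]:
                base["consequence"] = "nonsense"
        else:
            base.update(clinvar_class="not_reported", clinvar_review="none",
                        intervar_class="VUS", MetaLR=0.9, MetaSVM=0.8)
        rows.append(base)
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def cascade_relative_ids(carriers: pd.DataFrame) -> frozenset:
    """Participant ids flagged as cascade-screened proband relatives."""
    return frozenset(carriers.loc[carriers["cascade_relative"], "participant_id"])
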