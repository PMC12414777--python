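"""Carrier assignment, exclusion rules, penetrance and DLCN scoring.

Carriers are participants with at least one alternate allele of a classified
panel variant.  The analysis population removes carriers of two variants,
relatives hospitalised through family cascade screening, and carriers of the
APOB p.Gln4494del variant (not supported as FH-causal).  Penetrance is the
fraction of eligible carriers whose maximum recorded LDL-C — corrected to a
pre-treatment level for participants on lipid-lowering therapy — reaches a
gene-specific threshold: 4.0 mmol/L for LDLR, 4.9 mmol/L for APOB.
Undiagnosed carriers are screened with the Dutch Lipid Clinic Network score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CorrectionTable, DlcnTable, PENETRANCE_THRESHOLDS

PARTICIPANT_REQUIRED_COLUMNS = (
    "participant_id", "sex", "age", "bmi", "smoking", "diabetes",
    "alcohol_audit_c", "icd10_primary", "tc", "ldl", "hdl", "tg",
    "max_ldl_observed", "on_lipid_lowering", "therapy_class",
    "therapy_intensity", "prior_fh_diagnosis",
)

#: DLCN input flags a phenotype table may carry (absent columns score 0).
DLCN_INPUT_COLUMNS = (
    "fam_relative_premature_cvd", "fam_relative_high_ldl",
    "fam_relative_xanthoma_or_arcus", "fam_child_high_ldl",
    "premature_cad", "premature_cerebral_or_peripheral",
    "tendon_xanthoma", "arcus_cornealis_under_45",
)

EXCLUSION_REASONS = ("two_variants", "cascade_proband_relative", "q4494del_carrier", "none")

#: Carrier analysis groups reported throughout (penetrance and lipid tables).
CARRIER_GROUPS = ("all", "LDLR", "LDLR_PVLP", "LDLR_VUS_deleterious", "APOB")

PATHOGENIC_CLASSES = ("Pathogenic", "LikelyPathogenic", "VUS_deleterious")


class DegenerateGroupError(ValueError):
    """A carrier/non-carrier comparison group is empty."""


# ---------------------------------------------------------------------------
# Carrier assignment and exclusions
# ---------------------------------------------------------------------------

def assign_carriers(genotypes: pd.DataFrame, classified: pd.DataFrame) -> pd.DataFrame:
    """Build the carrier table from genotypes and classified variants.

    ``genotypes`` needs columns ``participant_id``, ``variant_id`` and
    ``n_alt`` (alternate-allele count); rows with ``n_alt`` 0 or missing are
    non-carrying records.  Only variants whose final class is Pathogenic,
    LikelyPathogenic or VUS_deleterious make a participant a carrier.

    Returns one row per carrier: the carried variant ids, genes and classes
    (semicolon-joined, ordered by variant id), ``n_variants``, and a
    ``two_variants`` flag.
    """
    for col in ("participant_id", "variant_id", "n_alt"):
        if col not in genotypes.columns:
            raise ValueError(f"genotype table missing column {col!r}")
    known = classified.set_index("variant_id")
    unknown = sorted(set(genotypes["variant_id"]) - set(known.index))
    if unknown:
        raise ValueError(f"genotypes reference unknown variant ids: {unknown}")

    carried = genotypes[genotypes["n_alt"].fillna(0).astype(int) > 0].copy()
    carried["gene"] = known.loc[carried["variant_id"], "gene"].to_numpy()
    carried["final_class"] = known.loc[carried["variant_id"], "final_class"].to_numpy()
    carried = carried[carried["final_class"].isin(PATHOGENIC_CLASSES)]
    carried = carried.sort_values(["participant_id", "variant_id"])

    rows = []
    for pid, grp in carried.groupby("participant_id", sort=True):
        rows.append({
            "participant_id": pid,
            "variant_ids": ";".join(grp["variant_id"]),
            "genes": ";".join(grp["gene"]),
            "classes": ";".join(grp["final_class"]),
            "n_variants": len(grp),
            "two_variants": len(grp) >= 2,
        })
    return pd.DataFrame(
        rows, columns=["participant_id", "variant_ids", "genes", "classes",
                       "n_variants", "two_variants"],
    )


def apply_exclusions(
    carrier_set: pd.DataFrame,
    cascade_relative_ids: set | frozenset = frozenset(),
    q4494del_variant_ids: set | frozenset = frozenset(),
) -> pd.DataFrame:
    """Apply the study exclusion rules and mark analysis eligibility.

    Reasons, in priority order: ``two_variants`` (carriers of two panel
    variants), ``cascade_proband_relative`` (relatives of probands
    hospitalised through family cascade screening — an external flag), and
    ``q4494del_carrier`` (APOB p.Gln4494del, not supported as FH-causal).
    Idempotent: re-applying the same flags changes nothing.
    """
    out = carrier_set.copy()
    reasons = []
    for _, row in out.iterrows():
        vids = set(str(row["variant_ids"]).split(";"))
        if row["two_variants"]:
            reasons.append("two_variants")
        elif row["participant_id"] in cascade_relative_ids:
            reasons.append("cascade_proband_relative")
        elif vids & set(q4494del_variant_ids):
            reasons.append("q4494del_carrier")
        else:
            reasons.append("none")
    out["exclusion_reason"] = reasons
    out["analysis_eligible"] = out["exclusion_reason"] == "none"
    return out


def carrier_group_mask(carrier_set: pd.DataFrame, group: str) -> pd.Series:
    """Boolean mask over eligible single-variant carriers for one report group."""
    if group not in CARRIER_GROUPS:
        raise ValueError(f"unknown carrier group {group!r}; expected one of {CARRIER_GROUPS}")
    eligible = carrier_set.get("analysis_eligible", pd.Series(True, index=carrier_set.index))
    if group == "all":
        return eligible.astype(bool)
    gene = carrier_set["genes"]
    cls = carrier_set["classes"]
    if group == "LDLR":
        return eligible & (gene == "LDLR")
    if group == "LDLR_PVLP":
        return eligible & (gene == "LDLR") & cls.isin(["Pathogenic", "LikelyPathogenic"])
    if group == "LDLR_VUS_deleterious":
        return eligible & (gene == "LDLR") & (cls == "VUS_deleterious")
    return eligible & (gene == "APOB")


# ---------------------------------------------------------------------------
# Pre-treatment LDL-C correction
# ---------------------------------------------------------------------------

def correct_pretreatment_ldl(
    observed: float,
    therapy_class: str,
    therapy_intensity: str,
    table: CorrectionTable | None = None,
) -> float:
    """Estimate the untreated LDL-C from an on-treatment measurement.

    Multiplies by the correction factor for the therapy the measurement was
    taken under; an unknown therapy raises rather than silently applying the
    identity.
    """
    if not np.isfinite(observed) or observed < 0:
        raise ValueError(f"observed LDL-C must be non-negative and finite, got {observed}")
    table = table or CorrectionTable()
    return observed * table.factor(therapy_class, therapy_intensity)


def corrected_max_ldl(
    participants: pd.DataFrame, table: CorrectionTable | None = None
) -> pd.Series:
    """Per-participant maximum LDL-C corrected for the therapy at that record."""
    table = table or CorrectionTable()
    out = {}
    for _, row in participants.iterrows():
        obs = row["max_ldl_observed"]
        if pd.isna(obs):
            out[row["participant_id"]] = np.nan
            continue
        if bool(row["on_lipid_lowering"]):
            val = correct_pretreatment_ldl(
                float(obs), str(row["therapy_class"]), str(row["therapy_intensity"]), table
            )
        else:
            val = float(obs)
        out[row["participant_id"]] = val
    return pd.Series(out, name="corrected_max_ldl")


# ---------------------------------------------------------------------------
# Penetrance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PenetranceResult:
    group: str
    threshold: float
    n: int
    n_above: int

    @property
    def penetrance(self) -> float:
        return self.n_above / self.n if self.n else float("nan")


def penetrance(
    carrier_set: pd.DataFrame,
    participants: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    correction_table: CorrectionTable | None = None,
) -> pd.DataFrame:
    """Penetrance per carrier group at both LDL-C thresholds.

    For every report group the fraction of eligible carriers with corrected
    maximum LDL-C at or above 4.0 and 4.9 mmol/L is reported, plus the
    gene-appropriate headline threshold (LDLR 4.0, APOB 4.9; mixed groups
    use each carrier's own gene threshold).  Carriers with no recorded
    maximum LDL-C are dropped with a logged count.
    """
    thresholds = thresholds or dict(PENETRANCE_THRESHOLDS)
    ldl = corrected_max_ldl(participants, correction_table)
    eligible = carrier_set[carrier_set["analysis_eligible"]] if "analysis_eligible" in carrier_set else carrier_set
    if eligible.empty:
        raise DegenerateGroupError("no analysis-eligible carriers")

    rows = []
    for group in CARRIER_GROUPS:
        mask = carrier_group_mask(carrier_set, group)
        members = carrier_set[mask]
        vals = ldl.reindex(members["participant_id"])
        n_missing = int(vals.isna().sum())
        vals = vals.dropna()
        genes = members.set_index("participant_id")["genes"].reindex(vals.index)
        for thr in (4.0, 4.9):
            rows.append({
                "group": group, "threshold": thr, "n": len(vals),
                "n_above": int((vals >= thr).sum()),
                "penetrance": (vals >= thr).mean() if len(vals) else np.nan,
                "n_missing_ldl": n_missing,
                "headline": False,
            })
        # gene-specific headline: each carrier judged at their own gene's threshold
        own_thr = genes.map(lambda g: thresholds.get(str(g).split(";")[0], np.nan))
        above = (vals >= own_thr).sum()
        rows.append({
            "group": group, "threshold": np.nan, "n": len(vals),
            "n_above": int(above),
            "penetrance": above / len(vals) if len(vals) else np.nan,
            "n_missing_ldl": n_missing,
            "headline": True,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DLCN scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DlcnsResult:
    family_history: int
    clinical_history: int
    physical_exam: int
    ldl_band: int
    dna: int
    total: int
    category: str

    def __post_init__(self) -> None:
        s = self.family_history + self.clinical_history + self.physical_exam + self.ldl_band + self.dna
        if s != self.total:
            raise ValueError("DLCN total must equal the sum of its components")


_GROUP_FLAGS = {
    "family_history": (
        ("fam_relative_premature_cvd", "relative_premature_cvd"),
        ("fam_relative_high_ldl", "relative_high_ldl"),
        ("fam_relative_xanthoma_or_arcus", "relative_xanthoma_or_arcus"),
        ("fam_child_high_ldl", "child_high_ldl"),
    ),
    "clinical_history": (
        ("premature_cad", "premature_cad"),
        ("premature_cerebral_or_peripheral", "premature_cerebral_or_peripheral"),
    ),
    "physical_exam": (
        ("tendon_xanthoma", "tendon_xanthoma"),
        ("arcus_cornealis_under_45", "arcus_cornealis_under_45"),
    ),
}


def dlcns_score(
    participant: pd.Series | dict,
    corrected_ldl: float,
    table: DlcnTable | None = None,
    causal_mutation: bool = False,
    include_dna: bool = True,
) -> DlcnsResult:
    """Dutch Lipid Clinic Network score for one participant.

    Within each criterion group only the highest-scoring positive item
    counts; missing inputs score 0.  ``include_dna=False`` scores the purely
    clinical criteria, which is how carriers are screened when the genetic
    finding itself must not count towards the diagnosis.
    """
    table = table or DlcnTable()

    def group_points(group: str) -> int:
        best = 0
        for col, item in _GROUP_FLAGS[group]:
            val = participant.get(col)  # works for both dict and Series
            if val is not None and not pd.isna(val) and bool(val):
                best = max(best, table.points[group][item])
        return best

    fam = group_points("family_history")
    clin = group_points("clinical_history")
    phys = group_points("physical_exam")
    ldl_pts = table.ldl_points(float(corrected_ldl))
    dna = table.points["dna"]["causal_mutation"] if (include_dna and causal_mutation) else 0
    total = fam + clin + phys + ldl_pts + dna
    return DlcnsResult(fam, clin, phys, ldl_pts, dna, total, table.category(total))


def fh_screen(
    carrier_set: pd.DataFrame,
    participants: pd.DataFrame,
    correction_table: CorrectionTable | None = None,
    dlcn_table: DlcnTable | None = None,
    criteria_min_points: int = 6,
) -> pd.DataFrame:
    """Screen eligible carriers for FH: prior diagnoses and DLCN-based ones.

    Returns one row per eligible carrier with the prior-diagnosis flag, the
    DLCN totals with and without the DNA criterion, and ``meets_criteria``:
    an undiagnosed carrier whose no-DNA DLCN total reaches
    ``criteria_min_points`` (probable or definite FH).
    """
    ldl = corrected_max_ldl(participants, correction_table)
    ppl = participants.set_index("participant_id")
    eligible = carrier_set[carrier_set["analysis_eligible"]] if "analysis_eligible" in carrier_set else carrier_set
    rows = []
    for _, row in eligible.iterrows():
        pid = row["participant_id"]
        person = ppl.loc[pid]
        prior = bool(person["prior_fh_diagnosis"])
        corrected = ldl.loc[pid]
        if pd.isna(corrected):
            corrected = 0.0
        with_dna = dlcns_score(person, corrected, dlcn_table, causal_mutation=True,
                               include_dna=True)
        no_dna = dlcns_score(person, corrected, dlcn_table, causal_mutation=True,
                             include_dna=False)
        rows.append({
            "participant_id": pid,
            "prior_fh_diagnosis": prior,
            "dlcns_with_dna": with_dna.total,
            "dlcns_without_dna": no_dna.total,
            "category_with_dna": with_dna.category,
            "category_without_dna": no_dna.category,
            "meets_criteria": (not prior) and no_dna.total >= criteria_min_points,
        })
    return pd.DataFrame(
        rows, columns=["participant_id", "prior_fh_diagnosis", "dlcns_with_dna",
                       "dlcns_without_dna", "category_with_dna",
                       "category_without_dna", "meets_criteria"],
    )
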