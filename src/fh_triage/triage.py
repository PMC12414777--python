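"""Rule-based triage of candidate FH variants.

Candidate variants in the LDLR/APOB/PCSK9 panel are first filtered on
region, type, gnomAD frequency and ClinVar benign status, and each survivor
is then assigned a final class by a deterministic decision tree that
integrates the ClinVar assertion and its review status, an InterVar-style
ACMG interpretation, an in-silico predictor consensus, and external
clinical-case evidence.  Every decision records which branch fired so a
reviewer can audit the path.

Final classes
-------------
``Pathogenic`` / ``LikelyPathogenic``
    ACMG-tier assertions kept or reached through the review path.
``VUS_deleterious``
    rare LDLR missense variants of uncertain significance that MetaLR and
    MetaSVM both predict to be deleterious (the study's "potentially
    deleterious" class).
``VUS``
    everything else that survives filtering.
``Excluded``
    removed by the candidate filter, with the first failing reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    CLINVAR_CLASSES,
    CLINVAR_REVIEWS,
    CONSEQUENCES,
    INTERVAR_CLASSES,
    PRIMARY_PREDICTORS,
    REGIONS,
    SCORE_RANGES,
    TriageConfig,
    VARIANT_TYPES,
)

PATHOGENIC_TIER = {"Pathogenic": 4, "LikelyPathogenic": 3, "VUS_deleterious": 2, "VUS": 1}

SCORE_FIELDS = ("SIFT", "PolyPhen2_HDIV", "MutationAssessor", "M_CAP", "CADD",
                "REVEL", "MetaLR", "MetaSVM")

ANNOTATION_COLUMNS = (
    "variant_id", "gene", "region", "variant_type", "consequence", "gnomad_maf",
    "clinvar_class", "clinvar_review", "intervar_class",
    *SCORE_FIELDS, "clinical_case_support",
)


@dataclass(frozen=True)
class VariantAnnotation:
    """One variant's pre-computed annotations (1-based GRCh38 coordinates)."""

    variant_id: str
    gene: str
    region: str
    variant_type: str
    consequence: str
    gnomad_maf: float | None  # None = not reported in gnomAD
    clinvar_class: str
    clinvar_review: str
    intervar_class: str
    scores: dict[str, float] = field(default_factory=dict)  # missing keys = missing
    clinical_case_support: bool = False

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"{self.variant_id}: unknown region {self.region!r}")
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"{self.variant_id}: unknown variant_type {self.variant_type!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"{self.variant_id}: unknown consequence {self.consequence!r}")
        if self.clinvar_class not in CLINVAR_CLASSES:
            raise ValueError(f"{self.variant_id}: unknown clinvar_class {self.clinvar_class!r}")
        if self.clinvar_review not in CLINVAR_REVIEWS:
            raise ValueError(f"{self.variant_id}: unknown clinvar_review {self.clinvar_review!r}")
        if self.intervar_class not in INTERVAR_CLASSES:
            raise ValueError(f"{self.variant_id}: unknown intervar_class {self.intervar_class!r}")
        if self.gnomad_maf is not None:
            if not math.isfinite(self.gnomad_maf) or not 0 <= self.gnomad_maf <= 1:
                raise ValueError(
                    f"{self.variant_id}: malformed gnomad_maf {self.gnomad_maf!r}"
                )
        for name, value in self.scores.items():
            lo, hi = SCORE_RANGES[name]
            if not math.isfinite(value) or not lo <= value <= hi:
                raise ValueError(
                    f"{self.variant_id}: score {name}={value!r} outside [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class ClassifiedVariant:
    variant_id: str
    gene: str
    final_class: str
    fired_branch: str
    exclusion_reason: str | None = None
    evidence_summary: str = ""

    def __post_init__(self) -> None:
        if (self.final_class == "Excluded") != (self.exclusion_reason is not None):
            raise ValueError("Excluded iff exclusion_reason present")


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------

#: Fixed rule order; an excluded variant carries its FIRST failing reason.
EXCLUSION_ORDER = ("gene", "region", "type", "maf", "benign_in_clinvar")


def _first_exclusion(ann: VariantAnnotation, config: TriageConfig) -> str | None:
    if ann.gene not in config.panel_genes:
        return "gene"
    if ann.region not in ("exonic", "splice_site"):
        return "region"
    if ann.variant_type not in ("SNV", "indel"):
        return "type"
    # variants absent from gnomAD are retained
    if ann.gnomad_maf is not None and ann.gnomad_maf >= config.maf_threshold:
        return "maf"
    if ann.clinvar_class in ("B", "LB"):
        return "benign_in_clinvar"
    return None


def filter_candidates(
    annotations: pd.DataFrame, config: TriageConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an annotation table into candidates and exclusions.

    Returns ``(candidates, excluded)``; ``excluded`` gains an
    ``exclusion_reason`` column.  The candidate *set* does not depend on
    input row order.
    """
    config = config or TriageConfig()
    anns = annotations_from_frame(annotations)
    reasons = [_first_exclusion(a, config) for a in anns]
    mask = np.array([r is None for r in reasons], dtype=bool)
    candidates = annotations.loc[mask].copy()
    excluded = annotations.loc[~mask].copy()
    excluded["exclusion_reason"] = [r for r in reasons if r is not None]
    return candidates, excluded


# ---------------------------------------------------------------------------
# In-silico evidence
# ---------------------------------------------------------------------------

def insilico_consensus(scores: dict[str, float], config: TriageConfig | None = None) -> dict:
    """Consensus over the five primary predictors.

    A predictor votes deleterious when present and past its cutoff
    (SIFT < 0.05, PolyPhen-2 HDIV >= 0.95, MutationAssessor >= 2,
    M-CAP > 0.025, CADD >= 15); agreement of three or more is in-silico
    evidence of likely-pathogenic status.  Missing scores never vote.
    """
    config = config or TriageConfig()
    votes = {
        "SIFT": lambda v: v < config.sift_max,
        "PolyPhen2_HDIV": lambda v: v >= config.polyphen_min,
        "MutationAssessor": lambda v: v >= config.mutation_assessor_min,
        "M_CAP": lambda v: v > config.m_cap_min,
        "CADD": lambda v: v >= config.cadd_min,
    }
    present = [p for p in PRIMARY_PREDICTORS if scores.get(p) is not None]
    n_agree = sum(1 for p in present if votes[p](scores[p]))
    return {
        "supports_LP": n_agree >= config.consensus_min_agree,
        "n_agree": n_agree,
        "evaluable": len(present) >= config.consensus_min_agree,
    }


def tiebreak_inconclusive(scores: dict[str, float], config: TriageConfig | None = None) -> bool:
    """REVEL > 0.75 and MetaLR > 0.5, both present; missing evidence is not evidence."""
    config = config or TriageConfig()
    revel, metalr = scores.get("REVEL"), scores.get("MetaLR")
    if revel is None or metalr is None:
        return False
    return revel > config.revel_min and metalr > config.metalr_min


# ---------------------------------------------------------------------------
# Classification decision tree
# ---------------------------------------------------------------------------

def _review_path(ann: VariantAnnotation, config: TriageConfig) -> tuple[str, str]:
    """Manual-review path shared by branches B-E.

    LikelyPathogenic when the in-silico consensus supports it or external
    clinical-case evidence exists; while the interpretation remains
    inconclusive (consensus not evaluable, or evaluable but short of the
    quorum) the REVEL/MetaLR tie-break is applied; otherwise VUS.  Applying
    the tie-break to every inconclusive outcome keeps the engine monotone:
    adding a passing score can never demote a variant.
    """
    cons = insilico_consensus(ann.scores, config)
    if ann.clinical_case_support:
        return "LikelyPathogenic", "clinical case support"
    if cons["supports_LP"]:
        return "LikelyPathogenic", f"consensus {cons['n_agree']}/5"
    if tiebreak_inconclusive(ann.scores, config):
        return "LikelyPathogenic", "REVEL/MetaLR tie-break"
    if cons["evaluable"]:
        return "VUS", f"consensus {cons['n_agree']}/5 insufficient; tie-break failed"
    return "VUS", "consensus not evaluable; tie-break failed"


def _rare_missense_deleterious(ann: VariantAnnotation, config: TriageConfig) -> bool:
    if ann.gene != "LDLR" or ann.consequence != "missense":
        return False
    if ann.gnomad_maf is not None and ann.gnomad_maf >= config.rare_missense_maf_threshold:
        return False
    metalr, metasvm = ann.scores.get("MetaLR"), ann.scores.get("MetaSVM")
    if metalr is None or metasvm is None:
        return False
    return metalr > config.metalr_min and metasvm > config.metasvm_min


def classify_variant(
    ann: VariantAnnotation, config: TriageConfig | None = None
) -> ClassifiedVariant:
    """Assign the final class to one candidate variant.

    Branches (recorded in ``fired_branch``):

    A. ClinVar P/LP with expert-panel or multiple-submitters review and an
       InterVar P/LP interpretation: the ClinVar class stands.
    B. ClinVar P/LP but InterVar VUS: manual-review path.
    C. ClinVar P with only single-submitter / criteria-not-provided review:
       Pathogenic only with clinical-case support plus in-silico or InterVar
       corroboration, otherwise the review-path outcome.
    D. ClinVar LP with weak review: review path.
    E. ClinVar VUS / unreported (or conflicting): InterVar P/LP with
       expert-panel review stands; InterVar P/LP otherwise goes to the
       review path; InterVar VUS falls through to F for LDLR, else VUS.
    F. Rare LDLR missense (MAF < 0.0005 or unreported) that MetaLR and
       MetaSVM both call deleterious: VUS_deleterious.
    """
    config = config or TriageConfig()
    cv, review, iv = ann.clinvar_class, ann.clinvar_review, ann.intervar_class
    full = {"P": "Pathogenic", "LP": "LikelyPathogenic"}

    conflict_note = ""
    if cv == "conflicting":
        # not addressed by the enumerated rules: treated as uncertain and
        # routed through branch E, flagged for manual review
        conflict_note = "conflicting ClinVar interpretations; "
        if review == "none":
            return ClassifiedVariant(
                ann.variant_id, ann.gene, "VUS", "E",
                evidence_summary="conflicting ClinVar class with no review status; "
                "flagged for manual review",
            )

    if cv in ("P", "LP"):
        strong_review = review in ("expert_panel", "multiple_submitters")
        if strong_review and iv in ("P", "LP"):
            return ClassifiedVariant(
                ann.variant_id, ann.gene, full[cv], "A",
                evidence_summary=f"ClinVar {cv}/{review} concordant with InterVar {iv}",
            )
        if iv == "VUS":
            cls, why = _review_path(ann, config)
            return ClassifiedVariant(
                ann.variant_id, ann.gene, cls, "B",
                evidence_summary=f"ClinVar {cv} vs InterVar VUS; {why}",
            )
        if cv == "P" and review in ("single_submitter", "criteria_not_provided", "none"):
            cons = insilico_consensus(ann.scores, config)
            corroborated = cons["supports_LP"] or iv in ("P", "LP")
            if ann.clinical_case_support and corroborated:
                return ClassifiedVariant(
                    ann.variant_id, ann.gene, "Pathogenic", "C",
                    evidence_summary="single-submitter P with clinical test support "
                    "and corroborating assessment",
                )
            cls, why = _review_path(ann, config)
            return ClassifiedVariant(
                ann.variant_id, ann.gene, cls, "C",
                evidence_summary=f"single-submitter P downgraded to review path; {why}",
            )
        if cv == "LP" and review in ("single_submitter", "criteria_not_provided", "none"):
            cls, why = _review_path(ann, config)
            return ClassifiedVariant(
                ann.variant_id, ann.gene, cls, "D",
                evidence_summary=f"LP with weak review status; {why}",
            )
        # strong review but InterVar B/LB/not_available: not enumerated by the
        # study rules; resolved through the review path for totality
        cls, why = _review_path(ann, config)
        return ClassifiedVariant(
            ann.variant_id, ann.gene, cls, "B",
            evidence_summary=f"ClinVar {cv} with InterVar {iv}; {why}",
        )

    # ClinVar VUS / not_reported / conflicting-with-review
    if iv in ("P", "LP"):
        if review == "expert_panel":
            return ClassifiedVariant(
                ann.variant_id, ann.gene, full[iv], "E",
                evidence_summary=conflict_note + f"InterVar {iv} kept (expert-panel review)",
            )
        cls, why = _review_path(ann, config)
        return ClassifiedVariant(
            ann.variant_id, ann.gene, cls, "E",
            evidence_summary=conflict_note + f"InterVar {iv} reviewed; {why}",
        )
    if ann.gene == "LDLR" and iv == "VUS" and ann.consequence == "missense":
        if _rare_missense_deleterious(ann, config):
            return ClassifiedVariant(
                ann.variant_id, ann.gene, "VUS_deleterious", "F",
                evidence_summary=conflict_note
                + "rare LDLR missense called deleterious by MetaLR and MetaSVM",
            )
        return ClassifiedVariant(
            ann.variant_id, ann.gene, "VUS", "F",
            evidence_summary=conflict_note + "rare LDLR missense without MetaLR/MetaSVM support",
        )
    return ClassifiedVariant(
        ann.variant_id, ann.gene, "VUS", "E",
        evidence_summary=conflict_note + f"ClinVar {cv}, InterVar {iv}: uncertain",
    )


# ---------------------------------------------------------------------------
# Table-level driver
# ---------------------------------------------------------------------------

def annotations_from_frame(frame: pd.DataFrame) -> list[VariantAnnotation]:
    """Validate a raw annotation table row-by-row.

    All malformed rows are reported together (index-tagged), not just the
    first one.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"annotation table missing required columns: {missing}")
    anns: list[VariantAnnotation] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        maf = row["gnomad_maf"]
        maf = None if pd.isna(maf) else float(maf)
        scores = {
            f: float(row[f]) for f in SCORE_FIELDS if not pd.isna(row[f])
        }
        ann = VariantAnnotation(
            variant_id=str(row["variant_id"]),
            gene=str(row["gene"]),
            region=str(row["region"]),
            variant_type=str(row["variant_type"]),
            consequence=str(row["consequence"]),
            gnomad_maf=maf,
            clinvar_class=str(row["clinvar_class"]),
            clinvar_review=str(row["clinvar_review"]),
            intervar_class=str(row["intervar_class"]),
            scores=scores,
            clinical_case_support=bool(row["clinical_case_support"]),
        )
        try:
            ann.validate()
        except ValueError as e:
            errors.append(f"row {idx}: {e}")
        anns.append(ann)
    if errors:
        raise ValueError("annotation validation failed:\n" + "\n".join(errors))
    return anns


def classify_all(
    annotations: pd.DataFrame, config: TriageConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter and classify a whole annotation table.

    Returns ``(classified, summary)`` where ``classified`` has one row per
    input variant (Excluded rows included, with reasons) and ``summary``
    counts final classes per gene.
    """
    config = config or TriageConfig()
    records = []
    if len(annotations):
        anns = annotations_from_frame(annotations)
        for ann in anns:
            reason = _first_exclusion(ann, config)
            if reason is not None:
                records.append(ClassifiedVariant(
                    ann.variant_id, ann.gene, "Excluded", "filter",
                    exclusion_reason=reason,
                    evidence_summary=f"excluded by {reason} filter",
                ))
            else:
                records.append(classify_variant(ann, config))
    classified = pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "gene": r.gene,
                "final_class": r.final_class,
                "fired_branch": r.fired_branch,
                "exclusion_reason": r.exclusion_reason,
                "evidence_summary": r.evidence_summary,
            }
            for r in records
        ],
        columns=["variant_id", "gene", "final_class", "fired_branch",
                 "exclusion_reason", "evidence_summary"],
    )
    if len(classified):
        summary = (
            classified.groupby(["gene", "final_class"]).size().rename("n").reset_index()
        )
    else:
        summary = pd.DataFrame(columns=["gene", "final_class", "n"])
    return classified, summary
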