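"""Configuration objects shared across the pipeline.

Everything tunable lives here: the variant-triage thresholds, the
lipid-lowering-therapy LDL-C correction factors, and the Dutch Lipid Clinic
Network (DLCN) point table.  All three can be serialised to / loaded from
YAML so a whole analysis is reproducible from one config file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Genes of the autosomal-dominant FH panel.
PANEL_GENES = ("LDLR", "APOB", "PCSK9")

#: Gene-specific maximum-LDL penetrance thresholds, mmol/L.
PENETRANCE_THRESHOLDS = {"LDLR": 4.0, "APOB": 4.9, "PCSK9": 4.0}

#: Controlled vocabularies for the annotation table.
CLINVAR_CLASSES = ("P", "LP", "VUS", "B", "LB", "conflicting", "not_reported")
CLINVAR_REVIEWS = (
    "expert_panel",
    "multiple_submitters",
    "single_submitter",
    "criteria_not_provided",
    "none",
)
INTERVAR_CLASSES = ("P", "LP", "VUS", "B", "LB", "not_available")
REGIONS = ("exonic", "splice_site", "other")
VARIANT_TYPES = ("SNV", "indel", "other")
CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe_del",
    "splice",
    "synonymous",
    "other",
)

#: The five primary in-silico predictors and their deleterious directions.
#: ("le" means a score at or below the cutoff supports pathogenicity.)
PRIMARY_PREDICTORS = ("SIFT", "PolyPhen2_HDIV", "MutationAssessor", "M_CAP", "CADD")

#: Plausibility ranges used only for input validation.
SCORE_RANGES = {
    "SIFT": (0.0, 1.0),
    "PolyPhen2_HDIV": (0.0, 1.0),
    "MutationAssessor": (-6.0, 6.0),
    "M_CAP": (0.0, 1.0),
    "CADD": (0.0, 99.0),
    "REVEL": (0.0, 1.0),
    "MetaLR": (0.0, 1.0),
    "MetaSVM": (-2.5, 3.5),
}


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds for candidate filtering and final classification.

    Defaults are the study values: panel restricted to LDLR/APOB/PCSK9,
    gnomAD MAF strictly below 0.01% (or absent), rare-missense rule below
    0.05%, and the published deleterious cutoffs of each predictor.
    """

    panel_genes: tuple[str, ...] = PANEL_GENES
    maf_threshold: float = 1e-4
    rare_missense_maf_threshold: float = 5e-4
    # primary consensus cutoffs
    sift_max: float = 0.05            # deleterious if SIFT < sift_max
    polyphen_min: float = 0.95        # deleterious if PolyPhen-2 HDIV >= polyphen_min
    mutation_assessor_min: float = 2.0  # deleterious if MA >= min
    m_cap_min: float = 0.025          # deleterious if M-CAP > m_cap_min
    cadd_min: float = 15.0            # deleterious if CADD >= cadd_min
    consensus_min_agree: int = 3
    # tie-breakers for inconclusive interpretations
    revel_min: float = 0.75           # REVEL > revel_min
    metalr_min: float = 0.5           # MetaLR > metalr_min
    # rare-missense deleteriousness rule (MetaLR / MetaSVM published cutoffs)
    metasvm_min: float = 0.0          # MetaSVM > 0 predicts deleterious
    # how a P vs LP disagreement among non-conflicting ClinVar submitters is
    # resolved upstream of this engine (documented choice; most severe wins)
    clinvar_severity_rule: str = "most_severe"
    splice_window_bp: int = 2

    def __post_init__(self) -> None:
        if self.maf_threshold <= 0 or self.rare_missense_maf_threshold <= 0:
            raise ValueError("MAF thresholds must be positive")
        if not 1 <= self.consensus_min_agree <= len(PRIMARY_PREDICTORS):
            raise ValueError(
                f"consensus_min_agree must be in [1, {len(PRIMARY_PREDICTORS)}]"
            )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["panel_genes"] = list(d["panel_genes"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TriageConfig":
        d = dict(d)
        if "panel_genes" in d:
            d["panel_genes"] = tuple(d["panel_genes"])
        return cls(**d)


# ---------------------------------------------------------------------------
# LDL-C pre-treatment correction factors
# ---------------------------------------------------------------------------
# Multiplicative factors applied to an on-treatment LDL-C measurement to
# estimate the untreated level, keyed by (drug class, intensity band).  The
# factor equals 1 / (1 - r) where r is the expected proportional LDL-C
# reduction of that regimen (e.g. a high-intensity statin lowering LDL-C by
# ~50% gives a factor of 2.0).  "none" is the identity.
DEFAULT_CORRECTION_FACTORS: dict[tuple[str, str], float] = {
    ("none", "none"): 1.0,
    ("statin", "low"): 1.43,            # ~30% reduction
    ("statin", "moderate"): 1.61,       # ~38% reduction
    ("statin", "high"): 2.00,           # ~50% reduction
    ("ezetimibe", "standard"): 1.24,    # ~19% reduction
    ("statin_ezetimibe", "moderate"): 1.85,  # ~46% reduction
    ("statin_ezetimibe", "high"): 2.38,      # ~58% reduction
    ("fibrate", "standard"): 1.09,      # ~8% reduction
    ("other", "standard"): 1.15,
}


@dataclass(frozen=True)
class CorrectionTable:
    """Maps (drug class, intensity) to a multiplicative LDL-C correction factor."""

    factors: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CORRECTION_FACTORS)
    )

    def __post_init__(self) -> None:
        for key, f in self.factors.items():
            if f < 1.0:
                raise ValueError(f"correction factor for {key} is < 1: {f}")
        if self.factors.get(("none", "none")) != 1.0:
            raise ValueError("the no-therapy factor must be the identity (1.0)")

    def factor(self, drug_class: str, intensity: str) -> float:
        key = (str(drug_class), str(intensity))
        if key not in self.factors:
            raise KeyError(
                f"therapy {key!r} not present in the correction table; "
                "add it to the table rather than assuming an identity factor"
            )
        return self.factors[key]

    def to_dict(self) -> dict[str, float]:
        return {f"{k[0]}/{k[1]}": v for k, v in self.factors.items()}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "CorrectionTable":
        factors = {}
        for key, v in d.items():
            drug, _, intensity = key.partition("/")
            factors[(drug, intensity)] = float(v)
        return cls(factors=factors)


# ---------------------------------------------------------------------------
# Dutch Lipid Clinic Network score
# ---------------------------------------------------------------------------
# Within each criterion group only the highest-scoring item counts; the total
# is the sum over groups.  LDL-C bands are on the (pre-treatment-corrected)
# maximum LDL-C in mmol/L.
DEFAULT_DLCN_POINTS: dict[str, dict[str, int]] = {
    "family_history": {
        "relative_premature_cvd": 1,
        "relative_high_ldl": 1,
        "relative_xanthoma_or_arcus": 2,
        "child_high_ldl": 2,
    },
    "clinical_history": {
        "premature_cad": 2,
        "premature_cerebral_or_peripheral": 1,
    },
    "physical_exam": {
        "tendon_xanthoma": 6,
        "arcus_cornealis_under_45": 4,
    },
    "dna": {"causal_mutation": 8},
}

#: LDL-C bands (lower bound mmol/L, points), highest band first.
DEFAULT_DLCN_LDL_BANDS: tuple[tuple[float, int], ...] = (
    (8.5, 8),
    (6.5, 5),
    (5.0, 3),
    (4.0, 1),
)

#: Category boundaries on the total: unlikely <3, possible 3-5, probable 6-8,
#: definite >8.
DEFAULT_DLCN_CATEGORIES: tuple[tuple[int, str], ...] = (
    (9, "definite"),
    (6, "probable"),
    (3, "possible"),
    (0, "unlikely"),
)


@dataclass(frozen=True)
class DlcnTable:
    """The DLCN point table and category boundaries."""

    points: dict[str, dict[str, int]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_DLCN_POINTS.items()}
    )
    ldl_bands: tuple[tuple[float, int], ...] = DEFAULT_DLCN_LDL_BANDS
    categories: tuple[tuple[int, str], ...] = DEFAULT_DLCN_CATEGORIES

    def ldl_points(self, ldl: float) -> int:
        if ldl < 0:
            raise ValueError(f"negative LDL-C: {ldl}")
        for lower, pts in self.ldl_bands:
            if ldl >= lower:
                return pts
        return 0

    def category(self, total: int) -> str:
        for lower, name in self.categories:
            if total >= lower:
                return name
        return self.categories[-1][1]


# ---------------------------------------------------------------------------
# YAML round-trip and hashing
# ---------------------------------------------------------------------------

def config_to_yaml(
    triage: TriageConfig,
    correction: CorrectionTable | None = None,
    dlcn: DlcnTable | None = None,
) -> str:
    doc: dict[str, Any] = {"triage": triage.to_dict()}
    if correction is not None:
        doc["correction_factors"] = correction.to_dict()
    if dlcn is not None:
        doc["dlcn"] = {
            "points": dlcn.points,
            "ldl_bands": [list(b) for b in dlcn.ldl_bands],
            "categories": [list(c) for c in dlcn.categories],
        }
    return yaml.safe_dump(doc, sort_keys=True)


def config_from_yaml(text: str) -> tuple[TriageConfig, CorrectionTable, DlcnTable]:
    doc = yaml.safe_load(text) or {}
    triage = TriageConfig.from_dict(doc.get("triage", {}))
    correction = (
        CorrectionTable.from_dict(doc["correction_factors"])
        if "correction_factors" in doc
        else CorrectionTable()
    )
    if "dlcn" in doc:
        d = doc["dlcn"]
        dlcn = DlcnTable(
            points={g: dict(v) for g, v in d["points"].items()},
            ldl_bands=tuple(tuple(b) for b in d["ldl_bands"]),
            categories=tuple(tuple(c) for c in d["categories"]),
        )
    else:
        dlcn = DlcnTable()
    return triage, correction, dlcn


def config_hash(*objs: Any) -> str:
    """Stable hash of configuration content, for the run manifest."""

    def norm(o: Any) -> Any:
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return norm(dataclasses.asdict(o))
        if isinstance(o, dict):
            return {str(k): norm(v) for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
        if isinstance(o, (list, tuple)):
            return [norm(v) for v in o]
        return o

    blob = json.dumps([norm(o) for o in objs], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
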