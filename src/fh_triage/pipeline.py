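"""End-to-end orchestration: triage -> carriers -> penetrance/DLCNS -> association.

A run is driven by one :class:`RunConfig`; every stage's inputs and outputs
are written as TSV next to a machine-readable JSON report and a provenance
manifest (config hash, seed, package version), and reruns with the same
config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import group_summary, ihd_model_spec, fit_logistic_or, lipid_or_models
from .config import CorrectionTable, DlcnTable, TriageConfig, config_hash
from .io import (prepare_model_frame, read_annotations, read_genotypes,
                 read_phenotypes, read_vcf)
from .phenotype import apply_exclusions, assign_carriers, fh_screen, penetrance
from .triage import classify_all

log = logging.getLogger("fh_triage")


@dataclass
class RunConfig:
    annotations: str
    genotypes: str  # long TSV or a .vcf file
    phenotypes: str
    outdir: str
    triage: TriageConfig = field(default_factory=TriageConfig)
    correction: CorrectionTable = field(default_factory=CorrectionTable)
    dlcn: DlcnTable = field(default_factory=DlcnTable)
    cascade_relative_ids: tuple[str, ...] = ()
    q4494del_variant_ids: tuple[str, ...] = ("APOB_Q4494DEL",)
    fit_ihd_models: bool = True
    fit_lipid_models: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("annotations", "genotypes", "phenotypes"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level,
                        format="%(name)s %(levelname)s %(message)s")

    # --- stage 1: triage ----------------------------------------------
    annotations = read_annotations(config.annotations)
    classified, class_summary = classify_all(annotations, config.triage)
    classified.to_csv(outdir / "classified_variants.tsv", sep="\t", index=False)
    n_in = len(annotations)
    n_excluded = int((classified["final_class"] == "Excluded").sum())
    excl_counts = (classified.loc[classified["final_class"] == "Excluded",
                                  "exclusion_reason"].value_counts().to_dict())
    for reason, n in sorted(excl_counts.items()):
        log.info("triage: %d variants excluded by %s filter", n, reason)
    log.info("triage: %d variants in, %d candidates classified", n_in, n_in - n_excluded)

    # --- stage 2: carriers --------------------------------------------
    if str(config.genotypes).endswith(".vcf"):
        genotypes = read_vcf(config.genotypes)
    else:
        genotypes = read_genotypes(config.genotypes)
    carrier_set = assign_carriers(genotypes, classified)
    carrier_set = apply_exclusions(
        carrier_set,
        cascade_relative_ids=frozenset(config.cascade_relative_ids),
        q4494del_variant_ids=frozenset(config.q4494del_variant_ids),
    )
    carrier_set.to_csv(outdir / "carriers.tsv", sep="\t", index=False)
    reason_counts = carrier_set["exclusion_reason"].value_counts().to_dict()
    for reason, n in sorted(reason_counts.items()):
        log.info("carriers: %d with exclusion status %s", n, reason)

    # --- stage 3: phenotype -------------------------------------------
    participants = read_phenotypes(config.phenotypes)
    pen = penetrance(carrier_set, participants, correction_table=config.correction)
    pen.to_csv(outdir / "penetrance.tsv", sep="\t", index=False)
    screen = fh_screen(carrier_set, participants, config.correction, config.dlcn)
    screen.to_csv(outdir / "fh_screen.tsv", sep="\t", index=False)

    # --- stage 4: association ----------------------------------------
    eligible_ids = set(carrier_set.loc[carrier_set["analysis_eligible"], "participant_id"])
    all_carrier_ids = set(carrier_set["participant_id"])
    excluded_ids = all_carrier_ids - eligible_ids
    analysis = participants[~participants["participant_id"].isin(excluded_ids)]
    frame = prepare_model_frame(analysis, eligible_ids)
    summary = group_summary(analysis, eligible_ids)
    summary.to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False)

    ihd_results = {}
    if config.fit_ihd_models:
        for m in (1, 2):
            spec = ihd_model_spec(m)
            res = fit_logistic_or(frame, spec)
            ihd_results[f"model_{m}"] = {
                "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "p_value": res.p_value,
                "covariates": list(res.covariates),
                "n_cases": res.n_cases, "n_total": res.n_total,
            }
    lipid_table = pd.DataFrame()
    if config.fit_lipid_models:
        lipid_table = lipid_or_models(frame, carrier_set)
        lipid_table.to_csv(outdir / "lipid_or.tsv", sep="\t", index=False)

    # --- report --------------------------------------------------------
    n_participants = len(participants)
    n_carriers = len(carrier_set)
    prevalence = n_carriers / n_participants if n_participants else float("nan")
    report = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config_hash(config.triage, config.correction,
                                       config.dlcn, config.cascade_relative_ids,
                                       config.q4494del_variant_ids),
        },
        "stages": {
            "triage": {
                "variants_in": n_in,
                "candidates": n_in - n_excluded,
                "excluded": n_excluded,
                "exclusion_reasons": excl_counts,
                "class_counts": {
                    f"{r.gene}:{r.final_class}": int(r.n)
                    for r in class_summary.itertuples()
                },
            },
            "carriers": {
                "participants": n_participants,
                "carriers_found": n_carriers,
                "eligible": int(carrier_set["analysis_eligible"].sum()),
                "excluded": int((~carrier_set["analysis_eligible"]).sum()),
                "exclusion_reasons": {k: int(v) for k, v in reason_counts.items()},
                "carrier_prevalence_pct": round(100 * prevalence, 2),
            },
        },
        "penetrance": pen.fillna("NA").to_dict(orient="records"),
        "fh_screen": {
            "n_screened": int(len(screen)),
            "prior_fh_diagnosis": int(screen["prior_fh_diagnosis"].sum()),
            "meets_criteria_post_hoc": int(screen["meets_criteria"].sum()),
        },
        "ihd_models": ihd_results,
        "lipid_or": lipid_table.to_dict(orient="records"),
    }
    # stage-count consistency: nothing silently dropped
    assert report["stages"]["triage"]["variants_in"] == (
        report["stages"]["triage"]["candidates"] + report["stages"]["triage"]["excluded"])
    assert report["stages"]["carriers"]["carriers_found"] == (
        report["stages"]["carriers"]["eligible"] + report["stages"]["carriers"]["excluded"])

    report = _round_floats(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    text = [
        f"fh-triage run (config {report['provenance']['config_hash']}, seed {config.seed})",
        f"carrier prevalence: {report['stages']['carriers']['carrier_prevalence_pct']}% "
        f"({n_carriers} of {n_participants})",
        f"analysis-eligible carriers: {report['stages']['carriers']['eligible']}",
        f"variants: {n_in} in, {n_in - n_excluded} candidates",
    ]
    if ihd_results:
        m1 = ihd_results["model_1"]
        text.append(
            "IHD OR (sex- and age-adjusted): "
            f"{m1['odds_ratio']:.2f} [{m1['ci_low']:.2f}; {m1['ci_high']:.2f}], "
            f"p = {m1['p_value']:.3g}"
        )
    (outdir / "report.txt").write_text("\n".join(text) + "\n")
    return report
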