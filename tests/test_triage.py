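"""Candidate filtering and the variant-classification decision tree."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fh_triage.config import TriageConfig
from fh_triage.synthetic import AnnotationSimParams, BRANCH_ARCHETYPES, generate_annotations
from fh_triage.triage import (ANNOTATION_COLUMNS, PATHOGENIC_TIER, VariantAnnotation,
                              classify_all, classify_variant, filter_candidates,
                              insilico_consensus, tiebreak_inconclusive)


def make_ann(**overrides) -> VariantAnnotation:
    base = dict(
        variant_id="19:11100000:A:G", gene="LDLR", region="exonic",
        variant_type="SNV", consequence="missense", gnomad_maf=None,
        clinvar_class="VUS", clinvar_review="single_submitter",
        intervar_class="VUS", scores={}, clinical_case_support=False,
    )
    base.update(overrides)
    return VariantAnnotation(**base)


ALL_DELETERIOUS = {"SIFT": 0.01, "PolyPhen2_HDIV": 0.99, "MutationAssessor": 2.5,
                   "M_CAP": 0.03, "CADD": 24.0}


class TestConsensus:
    @pytest.mark.parametrize("scores, n_agree, supports, evaluable", [
        (ALL_DELETERIOUS, 5, True, True),
        ({"SIFT": 0.01, "PolyPhen2_HDIV": 0.99}, 2, False, False),
        ({"SIFT": 0.01, "PolyPhen2_HDIV": 0.99, "MutationAssessor": 2.0,
          "M_CAP": 0.01, "CADD": 3.0}, 3, True, True),  # exactly three agree
        ({}, 0, False, False),
        ({"SIFT": 0.5, "PolyPhen2_HDIV": 0.2, "MutationAssessor": 0.0,
          "M_CAP": 0.001, "CADD": 5.0}, 0, False, True),
    ])
    def test_quorum_of_three(self, scores, n_agree, supports, evaluable):
        res = insilico_consensus(scores)
        assert res["n_agree"] == n_agree
        assert res["supports_LP"] is supports
        assert res["evaluable"] is evaluable

    @pytest.mark.parametrize("scores, expected", [
        ({"REVEL": 0.8, "MetaLR": 0.6}, True),
        ({"REVEL": 0.8, "MetaLR": 0.4}, False),
        ({"MetaLR": 0.6}, False),  # missing REVEL is not evidence
        ({"REVEL": 0.75, "MetaLR": 0.6}, False),  # strict inequality
    ])
    def test_tiebreak(self, scores, expected):
        assert tiebreak_inconclusive(scores) is expected


class TestFilter:
    @pytest.mark.parametrize("overrides, reason", [
        (dict(gnomad_maf=None, clinvar_class="VUS"), None),  # unreported stays in
        (dict(gnomad_maf=0.005), "maf"),
        (dict(gnomad_maf=0.0001), "maf"),  # strictly below the threshold required
        (dict(gene="APOB", gnomad_maf=5e-5, clinvar_class="LB"), "benign_in_clinvar"),
        (dict(region="other"), "region"),
        (dict(gene="APOE"), "gene"),
        (dict(variant_type="other"), "type"),
        (dict(gnomad_maf=9e-5), None),
    ])
    def test_first_failing_reason(self, overrides, reason):
        ann = make_ann(**overrides)
        frame = annotation_frame([ann])
        candidates, excluded = filter_candidates(frame)
        if reason is None:
            assert len(candidates) == 1 and len(excluded) == 0
        else:
            assert len(candidates) == 0
            assert excluded["exclusion_reason"].iloc[0] == reason

    def test_candidate_set_is_order_invariant(self):
        anns = generate_annotations(AnnotationSimParams(n_variants=60, seed=7))
        frame = anns[list(ANNOTATION_COLUMNS)]
        shuffled = frame.sample(frac=1.0, random_state=3)
        c1, _ = filter_candidates(frame)
        c2, _ = filter_candidates(shuffled)
        assert set(c1["variant_id"]) == set(c2["variant_id"])


def annotation_frame(anns) -> pd.DataFrame:
    rows = []
    for a in anns:
        row = {
            "variant_id": a.variant_id, "gene": a.gene, "region": a.region,
            "variant_type": a.variant_type, "consequence": a.consequence,
            "gnomad_maf": np.nan if a.gnomad_maf is None else a.gnomad_maf,
            "clinvar_class": a.clinvar_class, "clinvar_review": a.clinvar_review,
            "intervar_class": a.intervar_class,
            "clinical_case_support": a.clinical_case_support,
        }
        for f in ("SIFT", "PolyPhen2_HDIV", "MutationAssessor", "M_CAP", "CADD",
                  "REVEL", "MetaLR", "MetaSVM"):
            row[f] = a.scores.get(f, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


class TestClassification:
    @pytest.mark.parametrize("overrides, expected_class, expected_branch", [
        # concordant strong-review assertions keep the ClinVar class
        (dict(clinvar_class="P", clinvar_review="multiple_submitters",
              intervar_class="LP"), "Pathogenic", "A"),
        (dict(clinvar_class="LP", clinvar_review="expert_panel",
              intervar_class="P"), "LikelyPathogenic", "A"),
        # ClinVar P/LP vs InterVar VUS goes to review
        (dict(clinvar_class="P", clinvar_review="multiple_submitters",
              intervar_class="VUS", scores=ALL_DELETERIOUS), "LikelyPathogenic", "B"),
        (dict(clinvar_class="LP", clinvar_review="multiple_submitters",
              intervar_class="VUS"), "VUS", "B"),
        # single-submitter P needs clinical support plus corroboration
        (dict(clinvar_class="P", clinvar_review="single_submitter",
              intervar_class="LP", clinical_case_support=True), "Pathogenic", "C"),
        (dict(clinvar_class="P", clinvar_review="single_submitter",
              intervar_class="LB"), "VUS", "C"),
        (dict(clinvar_class="LP", clinvar_review="single_submitter",
              intervar_class="LP", scores=ALL_DELETERIOUS), "LikelyPathogenic", "D"),
        # ClinVar VUS with InterVar P/LP
        (dict(clinvar_class="VUS", clinvar_review="expert_panel",
              intervar_class="LP"), "LikelyPathogenic", "E"),
        (dict(clinvar_class="not_reported", clinvar_review="none",
              intervar_class="P", scores=ALL_DELETERIOUS), "LikelyPathogenic", "E"),
        # rare LDLR missense deleteriousness rule
        (dict(clinvar_class="VUS", intervar_class="VUS",
              scores={"MetaLR": 0.8, "MetaSVM": 0.9}), "VUS_deleterious", "F"),
        (dict(clinvar_class="VUS", intervar_class="VUS",
              scores={"MetaLR": 0.8, "MetaSVM": -0.5}), "VUS", "F"),
        (dict(clinvar_class="VUS", intervar_class="VUS", gnomad_maf=6e-5,
              scores={"MetaLR": 0.8, "MetaSVM": 0.9}), "VUS_deleterious", "F"),
        # non-LDLR uncertain variants never enter the rare-missense rule
        (dict(gene="APOB", clinvar_class="VUS", intervar_class="VUS",
              scores={"MetaLR": 0.8, "MetaSVM": 0.9}), "VUS", "E"),
        # conflicting ClinVar with no review: flagged, kept uncertain
        (dict(clinvar_class="conflicting", clinvar_review="none",
              intervar_class="P"), "VUS", "E"),
    ])
    def test_decision_branches(self, overrides, expected_class, expected_branch):
        cv = classify_variant(make_ann(**overrides))
        assert cv.final_class == expected_class
        assert cv.fired_branch == expected_branch

    def test_single_submitter_p_without_support_is_not_pathogenic(self):
        cv = classify_variant(make_ann(
            clinvar_class="P", clinvar_review="single_submitter",
            intervar_class="LP", clinical_case_support=False,
            scores={"SIFT": 0.9, "PolyPhen2_HDIV": 0.1, "MutationAssessor": 0.0,
                    "M_CAP": 0.001, "CADD": 2.0}))
        assert cv.final_class != "Pathogenic"

    def test_every_candidate_fires_exactly_one_branch(self):
        anns = generate_annotations(AnnotationSimParams(n_variants=150, seed=11))
        classified, _ = classify_all(anns[list(ANNOTATION_COLUMNS)])
        candidates = classified[classified["final_class"] != "Excluded"]
        assert candidates["fired_branch"].isin(list("ABCDEF")).all()
        assert (classified["final_class"].eq("Excluded")
                == classified["exclusion_reason"].notna()).all()

    def test_generator_ground_truth_recovered(self):
        anns = generate_annotations(AnnotationSimParams(n_variants=170, seed=5))
        classified, _ = classify_all(anns[list(ANNOTATION_COLUMNS)])
        merged = anns.merge(classified, on="variant_id", suffixes=("", "_out"))
        assert (merged["truth_class"] == merged["final_class"]).all()
        cand = merged[merged["truth_class"] != "Excluded"]
        assert (cand["truth_branch"] == cand["fired_branch"]).all()

    def test_empty_input(self):
        classified, summary = classify_all(pd.DataFrame(columns=ANNOTATION_COLUMNS))
        assert classified.empty and summary.empty

    def test_all_benign_pcsk9_yields_empty_gene_bucket(self):
        frame = annotation_frame([
            make_ann(variant_id=f"1:5503900{i}:A:G", gene="PCSK9",
                     clinvar_class="LB", intervar_class="LB") for i in range(4)
        ])
        classified, summary = classify_all(frame)
        assert (classified["final_class"] == "Excluded").all()
        assert summary.loc[summary["gene"] == "PCSK9", "final_class"].eq("Excluded").all()

    def test_malformed_rows_reported_with_indices(self):
        frame = annotation_frame([make_ann(), make_ann(variant_id="x")])
        frame.loc[1, "gnomad_maf"] = 3.0
        frame.loc[0, "clinvar_class"] = "weird"
        with pytest.raises(ValueError) as err:
            classify_all(frame)
        assert "row 0" in str(err.value) and "row 1" in str(err.value)


SCORE_STRATEGY = st.fixed_dictionaries({}, optional={
    "SIFT": st.floats(0, 1), "PolyPhen2_HDIV": st.floats(0, 1),
    "MutationAssessor": st.floats(-6, 6), "M_CAP": st.floats(0, 1),
    "CADD": st.floats(0, 99), "REVEL": st.floats(0, 1),
    "MetaLR": st.floats(0, 1), "MetaSVM": st.floats(-2.5, 3.5),
})

ANN_STRATEGY = st.builds(
    make_ann,
    gene=st.sampled_from(["LDLR", "APOB", "PCSK9"]),
    consequence=st.sampled_from(["missense", "nonsense", "frameshift", "splice"]),
    gnomad_maf=st.one_of(st.none(), st.floats(0, 9e-5)),
    clinvar_class=st.sampled_from(["P", "LP", "VUS", "conflicting", "not_reported"]),
    clinvar_review=st.sampled_from(["expert_panel", "multiple_submitters",
                                    "single_submitter", "criteria_not_provided", "none"]),
    intervar_class=st.sampled_from(["P", "LP", "VUS", "B", "LB", "not_available"]),
    scores=SCORE_STRATEGY,
    clinical_case_support=st.booleans(),
)


class TestProperties:
    @settings(max_examples=200, derandomize=True)
    @given(ann=ANN_STRATEGY)
    def test_deterministic(self, ann):
        a = classify_variant(ann)
        b = classify_variant(ann)
        assert (a.final_class, a.fired_branch) == (b.final_class, b.fired_branch)

    @settings(max_examples=200, derandomize=True)
    @given(ann=ANN_STRATEGY)
    def test_adding_clinical_support_never_demotes(self, ann):
        before = classify_variant(ann)
        strengthened = VariantAnnotation(**{**ann.__dict__, "clinical_case_support": True})
        after = classify_variant(strengthened)
        assert PATHOGENIC_TIER.get(after.final_class, 0) >= PATHOGENIC_TIER.get(before.final_class, 0)

    @settings(max_examples=200, derandomize=True)
    @given(ann=ANN_STRATEGY, predictor=st.sampled_from(
        ["SIFT", "PolyPhen2_HDIV", "MutationAssessor", "M_CAP", "CADD",
         "REVEL", "MetaLR", "MetaSVM"]))
    def test_adding_passing_score_never_demotes(self, ann, predictor):
        passing = {"SIFT": 0.01, "PolyPhen2_HDIV": 0.99, "MutationAssessor": 3.0,
                   "M_CAP": 0.1, "CADD": 25.0, "REVEL": 0.9, "MetaLR": 0.9,
                   "MetaSVM": 1.0}
        before = classify_variant(ann)
        scores = dict(ann.scores)
        scores[predictor] = passing[predictor]
        after = classify_variant(VariantAnnotation(**{**ann.__dict__, "scores": scores}))
        assert PATHOGENIC_TIER.get(after.final_class, 0) >= PATHOGENIC_TIER.get(before.final_class, 0)


def test_config_validation():
    with pytest.raises(ValueError):
        TriageConfig(consensus_min_agree=6)
    with pytest.raises(ValueError):
        TriageConfig(maf_threshold=-1)


def test_archetype_coverage():
    """Default generator mix reaches every decision branch and exclusion reason."""
    branches = {a["branch"] for a in BRANCH_ARCHETYPES.values()}
    assert branches >= set("ABCDEF")
    reasons = {a.get("reason") for a in BRANCH_ARCHETYPES.values()} - {None}
    assert reasons == {"maf", "benign_in_clinvar", "region", "gene"}
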