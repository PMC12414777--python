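# Methods

## Triage model

Triage is a pure function of a variant's pre-computed annotations. The
candidate filter applies its rules in a fixed order (gene → region → type →
MAF → ClinVar-benign) so each excluded variant carries one well-defined
first-failing reason; "below 0.01%" and "below 0.05%" are read strictly
(`<`), and variants absent from gnomAD are retained. Classification then
walks six branches:

* **A** — ClinVar P/LP with expert-panel or multiple-submitters review,
  concordant with an InterVar P/LP interpretation: the ClinVar class stands.
* **B** — ClinVar P/LP contradicted by InterVar VUS: manual-review path.
* **C** — ClinVar P with only single-submitter (or criteria-not-provided)
  review: Pathogenic only when external clinical-case evidence is present
  *and* corroborated by the in-silico consensus or InterVar; otherwise the
  review-path outcome. Since the engine does not re-run ACMG criteria, the
  "criteria-based assessment" is operationalised as that corroboration.
* **D** — ClinVar LP with weak review: review path.
* **E** — ClinVar VUS/unreported (and "conflicting", which the source rules
  do not address; treating it as uncertain is the conservative choice):
  an InterVar P/LP call with expert-panel review stands, otherwise the
  review path; InterVar VUS falls through to F for *LDLR*.
* **F** — rare *LDLR* missense (MAF < 0.0005 or unreported) called
  deleterious by both MetaLR (> 0.5) and MetaSVM (> 0, the tools'
  published cutoffs; configurable): *VUS predicted to be deleterious*.

The review path grants LikelyPathogenic on clinical-case support, on a
consensus of ≥ 3 of the five primary predictors, or — while the
interpretation remains inconclusive — on the REVEL/MetaLR tie-break.
Applying the tie-break to *every* inconclusive outcome (not only when too
few scores are present) keeps the engine monotone: adding a passing score
or clinical evidence can never demote a variant. ClinVar P/LP with strong
review but an InterVar benign/unavailable interpretation is not covered by
the enumerated source rules; it is routed through the review path so that
every candidate maps to exactly one branch.

Missing predictor scores never vote and never error; a missing score is
treated as absence of evidence, not evidence of benignity.

## Penetrance and LDL-C back-correction

Penetrance is the fraction of analysis-eligible carriers whose maximum
recorded LDL-C — multiplied, for measurements taken on therapy, by the
correction factor of that regimen — reaches the gene threshold (4.0 mmol/L
*LDLR*, 4.9 *APOB*). The shipped factor table maps (drug class, intensity)
to 1/(1 − r), r being the expected proportional LDL-C reduction of the
regimen (e.g. moderate-intensity statin r ≈ 0.38 → factor 1.61;
high-intensity ≈ 0.50 → 2.00); it is pure configuration, replaceable via
YAML, and an unknown regimen raises rather than silently applying the
identity. Tests rely only on the table's own values. Because two-variant
carriers are excluded, each analysis carrier has a single gene and hence an
unambiguous threshold; both thresholds are nevertheless reported for every
group. Correcting then thresholding at t is algebraically identical to
thresholding raw values at t/f for a uniform-therapy group, which the suite
checks.

## DLCN scoring

The Dutch Lipid Clinic Network table is shipped as configuration with the
standard published points: family-history items (1/1/2/2), clinical history
(premature CAD 2, premature cerebral/peripheral vascular disease 1),
physical signs (tendon xanthomata 6, arcus cornealis before 45 4), LDL-C
bands (≥ 8.5 → 8, 6.5–8.4 → 5, 5.0–6.4 → 3, 4.0–4.9 → 1) and DNA evidence
(8); within each group only the highest item counts, and categories are
unlikely < 3, possible 3–5, probable 6–8, definite > 8. Missing inputs
score zero. Because every carrier trivially reaches "definite" once the
genetic criterion counts, the post-hoc screening of undiagnosed carriers
uses the score *without* the DNA component, with probable-or-definite
(≥ 6 points) as the criterion; both totals are reported.

## Association

Categorical contrasts use Fisher's exact test (two-sided, the sum of
hypergeometric probabilities not exceeding the observed table's; sample OR
ad/bc with 0/∞ sentinels plus a Haldane–Anscombe companion), quantitative
contrasts the Mann–Whitney U (exact enumeration when both groups have ≤ 8
untied observations, otherwise the tie-corrected normal approximation).
Adjusted effects are maximum-likelihood logistic fits with Wald 95%
intervals and two-sided Wald p-values — Wald rather than profile intervals,
matching the symmetric-on-the-log-scale format the reported intervals take.
Perfect separation is detected per regressor and raised with the offending
column named; missing covariates are handled by complete-case analysis
with a logged count. Lipid models regress carrier-group membership on the
z-scored lipid with age (z), sex and any lipid-lowering therapy as
covariates, so lipid ORs are per standard deviation — the unit is a
documented assumption exposed in the model specification. Raw p-values
are reported (no multiplicity correction by default; Benjamini–Hochberg is
available to callers via statsmodels), and significance flags use strict
p < 0.05.

## Synthetic cohorts

`generate_cohort` draws carriers Bernoulli(prevalence), sex at 43% female,
age truncated-normal on [18, 100] (mean 65, sd 11 — only medians/IQRs are
known for the real cohort, so a symmetric family matching them is assumed),
and IHD from a logistic model whose carrier log-odds is ln(OR_true) plus
sex and standardised-age terms; defaults are the study conditions
(n = 4,856, prevalence 86/4,856, OR_true = 1.31). BMI, diabetes and smoking
effects default to zero so the sex/age model is correctly specified;
model-2 tests switch them on. Observed lipids are drawn per carrier status
around the printed medians with IQR-derived sds; the true maximum LDL-C of
treated participants (64.5%) is deflated by the same factor table the
phenotype module ships, making back-correction exactly invertible in
tests. The generator emulates marginal structure only — no correlation
between lipids and age/BMI, no longitudinal records, no linkage between
carried variant and effect size — so passing recovery tests demonstrates
the estimators, not realism of the joint distribution.

`generate_annotations` samples archetype rows, one per decision-branch
outcome (and one per exclusion reason), with predictor scores drawn
uniformly inside deleterious or benign strata, each row tagged with the
class the engine must output; triage is required to reproduce 100% of the
labels.

`build_table_fixtures` (fixed documented seed 20250928) reconstructs a
4,856-participant cohort whose constrained cells equal the printed counts
and quartiles exactly; see `fixtures/README.md` for which cells are pinned
and for the two documented reconciliations (cascade relatives counted as
2; a 51-member PV/LPV screening group). Quartile-constrained continuous
columns are built by pinning the percentile anchor indices of a sorted
array and interpolating between them, then shuffling.

## Numerical choices and problem sizes

* Odds-ratio recovery runs 200 replicates of n = 50,000 at prevalence
  0.016 and accepts a mean within 3× the replicate standard error of the
  generative OR; per-replicate seeds derive from one seed via
  `SeedSequence`.
* Type-I error is simulated with 10⁴ replicates: Mann–Whitney on two
  N(0, 1) groups of 50 must reject at the nominal 5% within a 99.9%
  binomial interval; Fisher's exact test on two binomial(40, 0.3) groups
  is conservative by construction (discrete support), so its rate is
  bounded above by the nominal level rather than equal to it.
* Exhaustive oracles: Fisher p-values are compared against direct
  hypergeometric enumeration, small-sample Mann–Whitney against
  enumeration over all C(8,4) group assignments.
* Logistic fits cap at 100 Newton iterations and raise on non-convergence;
  degenerate groups (empty, or below the configurable n = 5 minimum for
  lipid models) raise or are skipped with a warning, never silently.

## Limitations

The engine consumes interpretations (ClinVar, InterVar) as inputs and does
not re-evaluate ACMG criteria; ClinVar P-vs-LP disagreements among
non-conflicting submitters must be resolved upstream (the documented
default is most-severe). The fixtures constrain printed marginals only, so
fixture-based association contrasts (e.g. the unadjusted IHD odds ratio)
do not — and are not expected to — reproduce adjusted effect sizes
estimated on individual-level data. Homozygous-FH severity grading and
pediatric criteria are out of scope.
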