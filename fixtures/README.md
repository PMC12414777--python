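# Study-table fixtures

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
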