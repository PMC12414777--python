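variant_id	gene	final_class	fired_branch	exclusion_reason	evidence_summary	chrom	pos	ref	alt
LDLR_PV_01	LDLR	Pathogenic	A		synthetic fixture variant	19	11089000	G	A
LDLR_PV_02	LDLR	LikelyPathogenic	A		synthetic fixture variant	19	11089150	G	A
LDLR_PV_03	LDLR	Pathogenic	A		synthetic fixture variant	19	11089300	G	A
LDLR_PV_04	LDLR	LikelyPathogenic	A		synthetic fixture variant	19	11089450	G	A
LDLR_PV_05	LDLR	Pathogenic	A		synthetic fixture variant	19	11089600	G	A
LDLR_PV_06	LDLR	LikelyPathogenic	A		synthetic fixture variant	19	11089750	G	A
LDLR_PV_07	LDLR	Pathogenic	A		synthetic fixture variant	19	11089900	G	A
LDLR_PV_08	LDLR	LikelyPathogenic	A		synthetic fixture variant	19	11090050	G	A
LDLR_PV_09	LDLR	Pathogenic	A		synthetic fixture variant	19	11090200	G	A
LDLR_PV_10	LDLR	LikelyPathogenic	A		synthetic fixture variant	19	11090350	G	A
LDLR_PV_11	LDLR	Pathogenic	A		synthetic fixture variant	19	11090500	G	A
LDLR_PV_12	LDLR	LikelyPathogenic	A		synthetic fixture variant	19	11090650	G	A
LDLR_PV_13	LDLR	Pathogenic	A		synthetic fixture variant	19	11090800	G	A
LDLR_PV_14	LDLR	LikelyPathogenic	A		synthetic fixture variant	19	11090950	G	A
LDLR_PV_15	LDLR	Pathogenic	A		synthetic fixture variant	19	11091100	G	A
LDLR_PV_16	LDLR	LikelyPathogenic	A		synthetic fixture variant	19	11091250	G	A
LDLR_PV_17	LDLR	Pathogenic	A		synthetic fixture variant	19	11091400	G	A
LDLR_PV_18	LDLR	LikelyPathogenic	A		synthetic fixture variant	19	11091550	G	A
LDLR_PV_19	LDLR	Pathogenic	A		synthetic fixture variant	19	11091700	G	A
LDLR_PV_20	LDLR	LikelyPathogenic	A		synthetic fixture variant	19	11091850	G	A
LDLR_PV_21	LDLR	Pathogenic	A		synthetic fixture variant	19	11092000	G	A
LDLR_PV_22	LDLR	LikelyPathogenic	A		synthetic fixture variant	19	11092150	G	A
LDLR_PV_23	LDLR	Pathogenic	A		synthetic fixture variant	19	11092300	G	A
LDLR_PV_24	LDLR	LikelyPathogenic	A		synthetic fixture variant	19	11092450	G	A
LDLR_PV_25	LDLR	Pathogenic	A		synthetic fixture variant	19	11092600	G	A
LDLR_PV_26	LDLR	LikelyPathogenic	A		synthetic fixture variant	19	11092750	G	A
LDLR_PV_27	LDLR	Pathogenic	A		synthetic fixture variant	19	11092900	G	A
LDLR_VD_01	LDLR	VUS_deleterious	F		synthetic fixture variant	19	11093050	G	A
LDLR_VD_02	LDLR	VUS_deleterious	F		synthetic fixture variant	19	11093200	G	A
LDLR_VD_03	LDLR	VUS_deleterious	F		synthetic fixture variant	19	11093350	G	A
LDLR_VD_04	LDLR	VUS_deleterious	F		synthetic fixture variant	19	11093500	G	A
LDLR_VD_05	LDLR	VUS_deleterious	F		synthetic fixture variant	19	11093650	G	A
LDLR_VD_06	LDLR	VUS_deleterious	F		synthetic fixture variant	19	11093800	G	A
LDLR_VD_07	LDLR	VUS_deleterious	F		synthetic fixture variant	19	11093950	G	A
LDLR_VD_08	LDLR	VUS_deleterious	F		synthetic fixture variant	19	11094100	G	A
LDLR_VD_09	LDLR	VUS_deleterious	F		synthetic fixture variant	19	11094250	G	A
LDLR_VD_10	LDLR	VUS_deleterious	F		synthetic fixture variant	19	11094400	G	A
LDLR_VD_11	LDLR	VUS_deleterious	F		synthetic fixture variant	19	11094550	G	A
LDLR_VD_12	LDLR	VUS_deleterious	F		synthetic fixture variant	19	11094700	G	A
LDLR_VD_13	LDLR	VUS_deleterious	F		synthetic fixture variant	19	11094850	G	A
LDLR_VD_14	LDLR	VUS_deleterious	F		synthetic fixture variant	19	11095000	G	A
LDLR_VD_15	LDLR	VUS_deleterious	F		synthetic fixture variant	19	11095150	G	A
APOB_R3527Q	APOB	Pathogenic	A		synthetic fixture variant	2	21006300	G	A
APOB_Q4494DEL	APOB	LikelyPathogenic	B		synthetic fixture variant	2	21006450	G	A
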