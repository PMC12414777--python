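participant_id	variant_id	n_alt
FH0001	LDLR_PV_01	1
FH0002	LDLR_PV_02	1
FH0003	LDLR_PV_03	1
FH0004	LDLR_PV_04	1
FH0005	LDLR_PV_05	1
FH0006	LDLR_PV_06	1
FH0007	LDLR_PV_07	1
FH0008	LDLR_PV_08	1
FH0009	LDLR_PV_09	1
FH0010	LDLR_PV_10	1
FH0011	LDLR_PV_11	1
FH0012	LDLR_PV_12	1
FH0013	LDLR_PV_13	1
FH0014	LDLR_PV_14	1
FH0015	LDLR_PV_15	1
FH0016	LDLR_PV_16	1
FH0017	LDLR_PV_17	1
FH0018	LDLR_PV_18	1
FH0019	LDLR_PV_19	1
FH0020	LDLR_PV_20	1
FH0021	LDLR_PV_21	1
FH0022	LDLR_PV_22	1
FH0023	LDLR_PV_23	1
FH0024	LDLR_PV_24	1
FH0025	LDLR_PV_25	1
FH0026	LDLR_PV_26	1
FH0027	LDLR_PV_27	1
FH0028	LDLR_PV_01	1
FH0029	LDLR_PV_02	1
FH0030	LDLR_PV_03	1
FH0031	LDLR_PV_04	1
FH0032	LDLR_PV_05	1
FH0033	LDLR_PV_06	1
FH0034	LDLR_PV_07	1
FH0035	LDLR_PV_08	1
FH0036	LDLR_PV_09	1
FH0037	LDLR_PV_10	1
FH0038	LDLR_VD_01	1
FH0039	LDLR_VD_02	1
FH0040	LDLR_VD_03	1
FH0041	LDLR_VD_04	1
FH0042	LDLR_VD_05	1
FH0043	LDLR_VD_06	1
FH0044	LDLR_VD_07	1
FH0045	LDLR_VD_08	1
FH0046	LDLR_VD_09	1
FH0047	LDLR_VD_10	1
FH0048	LDLR_VD_11	1
FH0049	LDLR_VD_12	1
FH0050	LDLR_VD_13	1
FH0051	LDLR_VD_14	1
FH0052	LDLR_VD_15	1
FH0053	LDLR_VD_01	1
FH0054	LDLR_VD_02	1
FH0055	LDLR_VD_03	1
FH0056	LDLR_VD_04	1
FH0057	LDLR_VD_05	1
FH0058	LDLR_VD_06	1
FH0059	LDLR_VD_07	1
FH0060	LDLR_VD_08	1
FH0061	LDLR_VD_09	1
FH0062	APOB_R3527Q	1
FH0063	APOB_R3527Q	1
FH0064	APOB_R3527Q	1
FH0065	APOB_R3527Q	1
FH0066	APOB_R3527Q	1
FH0067	APOB_R3527Q	1
FH0068	APOB_R3527Q	1
FH0069	APOB_R3527Q	1
FH0070	APOB_R3527Q	1
FH0071	APOB_R3527Q	1
FH0072	APOB_R3527Q	1
FH0073	APOB_R3527Q	1
FH0074	APOB_R3527Q	1
FH0075	APOB_R3527Q	1
FH0076	APOB_R3527Q	1
FH0077	LDLR_PV_11	1
FH0077	LDLR_PV_12	1
FH0078	LDLR_PV_13	1
FH0078	LDLR_PV_14	1
FH0079	LDLR_PV_15	1
FH0079	LDLR_PV_16	1
FH0080	LDLR_PV_17	1
FH0080	LDLR_PV_18	1
FH0081	LDLR_PV_19	1
FH0082	LDLR_PV_20	1
FH0083	APOB_Q4494DEL	1
FH0084	APOB_Q4494DEL	1
FH0085	APOB_Q4494DEL	1
FH0086	APOB_Q4494DEL	1
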