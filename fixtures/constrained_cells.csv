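cell,value
eligible carriers,76
non-carriers,4770
total participants,4856
carriers incl. excluded,86
subgroup LDLR,61
subgroup LDLR PV/LP,37
subgroup LDLR VUS-deleterious,24
subgroup APOB,15
carriers corrected max LDL >= 4.0,55
carriers corrected max LDL >= 4.9,40
carriers with prior FH diagnosis,8
carriers meeting FH criteria post hoc,12
carriers with IHD history,61
carriers with I20-I25 code,60
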