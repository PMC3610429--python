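# Curated inventory of protein-translocation factors (130 rows), reconstructed
# from the published literature survey of yeast and Arabidopsis translocation
# machineries.  Factor names and compartments are genuine; bait accessions are
# SYNTHETIC placeholders except where the literature prints them (AGI / SGD ids).
# Species tags: sc = Saccharomyces cerevisiae, at = Arabidopsis thaliana.
factor_name	compartment	baits	literature_only
Srp9	ER	sc|SC_SRP9	false
Srp14	ER	sc|SC_SRP14	false
Srp21	ER	sc|SC_SRP21	false
Srp54	ER	sc|SC_SRP54	false
Srp68	ER	sc|SC_SRP68	false
Srp72	ER	sc|SC_SRP72	false
Sec65	ER	sc|SC_SEC65	false
SRalpha	ER	sc|SC_SRALPHA	false
SRbeta	ER	sc|SC_SRBETA	false
Sec61	ER	sc|SC_SEC61	false
Sbh1	ER	sc|SC_SBH1	false
Sbh2	ER	sc|SC_SBH2	false
Sss1	ER	sc|SC_SSS1	false
Ssh1	ER	sc|SC_SSH1	false
Sec62	ER	sc|SC_SEC62	false
Sec63	ER	sc|SC_SEC63	false
Sec71	ER	sc|SC_SEC71	false
Sec72	ER	sc|SC_SEC72	false
BiP	ER	sc|SC_BIP	false
Sgt2	ER	sc|SC_SGT2	false
Get1	ER	sc|SC_GET1	false
Get2	ER	sc|SC_GET2	false
Get3	ER	sc|SC_GET3	false
Get4	ER	sc|SC_GET4	false
Get5	ER	sc|SC_GET5	false
TPR7	ER	at|AT5G21990	true
Doa10	ERAD	sc|SC_DOA10	false
Ubc6	ERAD	sc|SC_UBC6	false
Ubc7	ERAD	sc|SC_UBC7	false
Cue1	ERAD	sc|SC_CUE1	false
Hrd1	ERAD	sc|SC_HRD1	false
Hrd3	ERAD	sc|SC_HRD3	false
Usa1	ERAD	sc|SC_USA1	false
Der1	ERAD	sc|SC_DER1	false
Dfm1	ERAD	sc|SC_DFM1,at|AT4G29330	false
Cdc48	ERAD	sc|SC_CDC48	false
Npl4	ERAD	sc|YBR170C,at|AT2G47970	true
Ufd1	ERAD	sc|SC_UFD1	false
Ubx2	ERAD	sc|YML013W	true
Pex1	peroxisome	sc|SC_PEX1	false
Pex2	peroxisome	sc|SC_PEX2	false
Pex3	peroxisome	at|AT3G18160,sc|SC_PEX3	false
Pex4	peroxisome	sc|SC_PEX4	false
Pex5	peroxisome	sc|SC_PEX5	false
Pex6	peroxisome	sc|SC_PEX6	false
Pex7	peroxisome	sc|SC_PEX7	false
Pex10	peroxisome	sc|SC_PEX10	false
Pex12	peroxisome	sc|SC_PEX12	false
Pex13	peroxisome	sc|SC_PEX13	false
Pex14	peroxisome	sc|SC_PEX14	false
Pex15	peroxisome	at|AT3G10572,sc|SC_PEX15	true
Pex17	peroxisome	sc|SC_PEX17	false
Pex18	peroxisome	sc|SC_PEX18	false
Pex19	peroxisome	at|AT3G03490,sc|SC_PEX19	false
Pex21	peroxisome	sc|SC_PEX21	false
Pex22	peroxisome	sc|SC_PEX22	true
Ubc4	peroxisome	sc|SC_UBC4	false
Ubc5	peroxisome	sc|SC_UBC5	false
Tom20	mitochondrion	sc|SC_TOM20	true
Tom22	mitochondrion	sc|SC_TOM22	true
Tom40	mitochondrion	sc|SC_TOM40	false
Tom5	mitochondrion	sc|SC_TOM5	true
Tom6	mitochondrion	sc|SC_TOM6	false
Tom7	mitochondrion	sc|SC_TOM7	true
Tom70	mitochondrion	sc|YNL121C,sc|YHR117W	false
Tim50	mitochondrion	sc|SC_TIM50	false
Tim23	mitochondrion	sc|SC_TIM23	false
Tim21	mitochondrion	at|AT4G00026	true
Tim17	mitochondrion	sc|SC_TIM17	false
Tim44	mitochondrion	sc|SC_TIM44	false
Pam16	mitochondrion	sc|SC_PAM16	false
Pam17	mitochondrion	sc|SC_PAM17	false
Pam18	mitochondrion	sc|SC_PAM18	false
Mdj2	mitochondrion	sc|SC_MDJ2	false
mtHsp70	mitochondrion	sc|SC_MTHSP70	false
Tim54	mitochondrion	sc|SC_TIM54	false
Tim22	mitochondrion	sc|SC_TIM22	false
Tim18	mitochondrion	sc|SC_TIM18	false
Tim12	mitochondrion	sc|SC_TIM12	false
Tim9	mitochondrion	sc|SC_TIM9	false
Tim10	mitochondrion	sc|SC_TIM10	false
Tim8	mitochondrion	sc|SC_TIM8	false
Tim13	mitochondrion	sc|SC_TIM13	false
Oxa1	mitochondrion	sc|SC_OXA1	false
Mia40	mitochondrion	sc|SC_MIA40	false
Erv1	mitochondrion	sc|SC_ERV1	false
Hot13	mitochondrion	sc|SC_HOT13	false
Sam50	mitochondrion	sc|SC_SAM50	false
Sam35	mitochondrion	sc|SC_SAM35	false
Sam37	mitochondrion	sc|SC_SAM37	false
Mdm10	mitochondrion	sc|SC_MDM10	false
Mim1	mitochondrion	sc|SC_MIM1	false
OM64	mitochondrion	at|AT_OM64	false
Metaxin	mitochondrion	at|AT_METAXIN	false
Toc159	chloroplast	at|AT_TOC159	false
Toc132	chloroplast	at|AT_TOC132	false
Toc120	chloroplast	at|AT_TOC120	false
Toc90	chloroplast	at|AT_TOC90	false
Toc34	chloroplast	at|AT_TOC34	false
Toc33	chloroplast	at|AT_TOC33	false
Toc64	chloroplast	at|AT_TOC64	false
Toc75-III	chloroplast	at|AT_TOC75_III	false
Toc75-IV	chloroplast	at|AT_TOC75_IV	false
Toc12	chloroplast	at|AT_TOC12	false
Tic110	chloroplast	at|AT_TIC110	false
Tic62	chloroplast	at|AT_TIC62	false
Tic55	chloroplast	at|AT_TIC55	false
Tic40	chloroplast	at|AT_TIC40	false
Tic32	chloroplast	at|AT_TIC32	false
Tic22	chloroplast	at|AT_TIC22	false
Tic21	chloroplast	at|AT_TIC21	false
Tic20-I	chloroplast	at|AT_TIC20_I	false
Tic20-II	chloroplast	at|AT_TIC20_II	false
Tic20-IV	chloroplast	at|AT_TIC20_IV	false
Tic20-V	chloroplast	at|AT_TIC20_V	false
imsHsp70	chloroplast	at|AT_IMSHSP70	false
stHsp70	chloroplast	at|AT_STHSP70	false
stHsp93	chloroplast	at|AT_STHSP93	false
cpSecA2	chloroplast	at|AT1G21650,at|AT1G21651	false
cpSecY2	chloroplast	at|AT_CPSECY2	false
cpSecA	thylakoid	at|AT_CPSECA	false
cpSecY	thylakoid	at|AT_CPSECY	false
cpSecE	thylakoid	at|AT_CPSECE	false
Alb3	thylakoid	at|AT_ALB3	false
cpSRP54	thylakoid	at|AT_CPSRP54	false
cpSRP43	thylakoid	at|AT_CPSRP43	false
cpFtsY	thylakoid	at|AT_CPFTSY	false
cpTatC	thylakoid	at|AT_CPTATC	false
Hcf106	thylakoid	at|AT_HCF106	false
Tha4	thylakoid	at|AT_THA4	false
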