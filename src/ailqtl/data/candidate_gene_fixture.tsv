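# Synthetic fixture: per-gene prioritization evidence for the seven top body-weight
# candidate genes of the BFMI861-S1 x BFMI861-S2 cross (Chr 15: Gpt, Cbx6, Apol6,
# Apol8; Chr 16: Trap1, Rrn3, Mapk1), assembled from published summary statistics.
# Checkmark-to-gene assignment of the regulatory categories is typographically
# ambiguous in the source table; where ambiguous it follows the Results prose:
#   - Gpt, Cbx6, Apol8: variants in UTRs, promoter, CTCF binding and splice sites.
#   - Apol6: variants in UTRs, enhancer and splice site.
#   - Trap1, Mapk1: assigned UTR + splice-site regulatory variants ("numerous SNPs
#     in regulatory regions"); Rrn3's evidence is expression-driven.
# Expression p-values are BH-adjusted; empty cells mean "not determined" (Cbx6 is
# absent from the expression assay). Fold changes are S1/S2.
gene_id	chromosome	deleterious_domain_missense	tolerated_domain_missense	utr	promoter	enhancer	ctcf_binding	splice_site	fc_adipose	p_adipose_adj	fc_liver	p_liver_adj	kegg_member
Gpt	15	1	0	1	1	0	1	1	0.810	1.23e-07	0.965	2.79e-06	0
Cbx6	15	1	0	1	1	0	1	1					0
Apol6	15	1	0	1	0	1	0	1	0.847	3.87e-06	0.989	0.503	0
Apol8	15	1	0	1	1	0	1	1	0.990	0.531	1.002	0.887	0
Trap1	16	0	1	1	0	0	0	1	0.959	5.50e-05	0.995	0.426	0
Rrn3	16	0	1	0	0	0	0	0	0.943	2.05e-06	0.917	1.28e-06	0
Mapk1	16	0	0	1	0	0	0	1	1.014	4.74e-02	0.999	0.924	0
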