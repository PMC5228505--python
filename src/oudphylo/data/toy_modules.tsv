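module_id	kind	gene_id	is_core
M_GLYCOLYSIS	pathway_module	K001	0
M_GLYCOLYSIS	pathway_module	K002	0
M_GLYCOLYSIS	pathway_module	K003	1
M_GLYCOLYSIS	pathway_module	K004	1
M_GLYCOLYSIS	pathway_module	K005	1
M_GLYCOLYSIS	pathway_module	K006	0
M_GLYCOLYSIS	pathway_module	K007	0
M_GLYCOLYSIS	pathway_module	K008	0
M_GLYCOLYSIS	pathway_module	K009	0
M_GLYCOLYSIS	pathway_module	K010	0
M_PENTOSE	pathway_module	K011	0
M_PENTOSE	pathway_module	K012	1
M_PENTOSE	pathway_module	K013	0
M_PENTOSE	pathway_module	K014	0
M_TCA	pathway_module	K015	1
M_TCA	pathway_module	K016	1
M_TCA	pathway_module	K017	0
M_TCA	pathway_module	K018	0
M_TCA	pathway_module	K019	0
C_ATP_SYNTHESIS	structural_complex	M_GLYCOLYSIS	0
C_ATP_SYNTHESIS	structural_complex	M_PENTOSE	0
C_ATP_SYNTHESIS	structural_complex	M_TCA	0
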