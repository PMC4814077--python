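country,gdp_per_capita,life_expectancy,p_cv,p_cv_mort,p_ncv_mort,av_eff_cv,av_eff_ncv,p_ear_mono,p_ear_poly,antivenom_label
benin,751,44,0.85,0.15,0.273,0.793,0.436,0.033,0.033,Antivipmyn
burkina_faso,652,43,0.85,0.121,0.05,0.92,0.92,0.19,0.26,EchiTab-G/Plus
cameroon,1220,41,0.85,0.153,0.05,0.852,0.852,0.043,0.043,FAV Afrique
chad,1035,38,0.85,0.153,0.05,0.5643,0.5643,0.043,0.043,FAV Afrique
cote_divoire,1366,39,0.83,0.121,0.05,0.75,0.75,0.043,0.043,meta-analytic
gambia,509,44,0.40,0.143,0.05,0.75,0.75,0.043,0.043,meta-analytic
ghana,1646,45,0.85,0.121,0.05,0.852,0.852,0.043,0.043,FAV Afrique
guinea_bissau,576,41,0.40,0.15,0.273,0.75,0.436,0.043,0.043,meta-analytic
guinea_conakry,493,43,0.83,0.15,0.273,0.793,0.436,0.033,0.033,Antivipmyn
liberia,414,44,0.01,0.15,0.05,0.75,0.75,0.043,0.043,meta-analytic
mali,696,43,0.85,0.081,0.05,0.8148,0.8148,0.043,0.043,FAV Afrique
niger,385,44,0.85,0.15,0.05,0.75,0.75,0.043,0.043,meta-analytic
nigeria,2742,41,0.66,0.1583,0.05,0.92,0.92,0.19,0.26,EchiTab-G/Plus
senegal,1023,45,0.40,0.15,0.05,0.75,0.75,0.043,0.043,meta-analytic
sierra_leone,590,37,0.01,0.15,0.05,0.75,0.75,0.043,0.043,meta-analytic
togo,589,43,0.85,0.121,0.05,0.75,0.75,0.043,0.043,meta-analytic
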