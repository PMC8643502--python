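area_label	lobe
G_and_S_frontomargin	frontal
G_and_S_occipital_inf	occipital
G_and_S_paracentral	frontal
G_and_S_subcentral	frontal
G_and_S_transv_frontopol	frontal
G_and_S_cingul-Ant	none
G_and_S_cingul-Mid-Ant	none
G_and_S_cingul-Mid-Post	none
G_cingul-Post-dorsal	none
G_cingul-Post-ventral	none
G_cuneus	occipital
G_front_inf-Opercular	frontal
G_front_inf-Orbital	frontal
G_front_inf-Triangul	frontal
G_front_middle	frontal
G_front_sup	frontal
G_Ins_lg_and_S_cent_ins	none
G_insular_short	none
G_occipital_middle	occipital
G_occipital_sup	occipital
G_oc-temp_lat-fusifor	occipital
G_oc-temp_med-Lingual	occipital
G_oc-temp_med-Parahip	temporal
G_orbital	frontal
G_pariet_inf-Angular	parietal
G_pariet_inf-Supramar	parietal
G_parietal_sup	parietal
G_postcentral	parietal
G_precentral	frontal
G_precuneus	parietal
G_rectus	frontal
G_subcallosal	none
G_temp_sup-G_T_transv	temporal
G_temp_sup-Lateral	temporal
G_temp_sup-Plan_polar	temporal
G_temp_sup-Plan_tempo	temporal
G_temporal_inf	temporal
G_temporal_middle	temporal
Lat_Fis-ant-Horizont	none
Lat_Fis-ant-Vertical	none
Lat_Fis-post	parietal
Pole_occipital	occipital
Pole_temporal	temporal
S_calcarine	occipital
S_central	frontal
S_cingul-Marginalis	parietal
S_circular_insula_ant	none
S_circular_insula_inf	none
S_circular_insula_sup	none
S_collat_transv_ant	temporal
S_collat_transv_post	occipital
S_front_inf	frontal
S_front_middle	frontal
S_front_sup	frontal
S_interm_prim-Jensen	parietal
S_intrapariet_and_P_trans	parietal
S_oc_middle_and_Lunatus	occipital
S_oc_sup_and_transversal	occipital
S_occipital_ant	occipital
S_oc-temp_lat	occipital
S_oc-temp_med_and_Lingual	occipital
S_orbital_lateral	frontal
S_orbital_med-olfact	frontal
S_orbital-H_Shaped	frontal
S_parieto_occipital	parietal
S_pericallosal	none
S_postcentral	parietal
S_precentral-inf-part	frontal
S_precentral-sup-part	frontal
S_suborbital	frontal
S_subparietal	parietal
S_temporal_inf	temporal
S_temporal_sup	temporal
S_temporal_transverse	temporal
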