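parcel,class,thickness_mm
G_cingul-Post-dorsal,gyral,3.14
G_cingul-Post-ventral,gyral,2.36
G_cuneus,gyral,2.15
G_front_inf-Opercular,gyral,3.09
G_front_inf-Orbital,gyral,3.08
G_front_inf-Triangul,gyral,2.92
G_front_middle,gyral,2.90
G_front_sup,gyral,3.08
G_Ins_lg_and_S_cent_ins,gyral,3.31
G_insular_short,gyral,3.73
G_occipital_middle,gyral,2.86
G_occipital_sup,gyral,2.45
G_oc-temp_lat-fusifor,gyral,3.14
G_oc-temp_med-Lingual,gyral,2.23
G_oc-temp_med-Parahip,gyral,3.18
G_orbital,gyral,2.97
G_pariet_inf-Angular,gyral,2.97
G_pariet_inf-Supramar,gyral,2.96
G_parietal_sup,gyral,2.56
G_postcentral,gyral,2.42
G_precentral,gyral,2.97
G_precuneus,gyral,2.85
G_rectus,gyral,2.74
G_subcallosal,gyral,2.78
G_temp_sup-G_T_transv,gyral,2.84
G_temp_sup-Lateral,gyral,3.27
G_temp_sup-Plan_polar,gyral,3.40
G_temp_sup-Plan_tempo,gyral,2.83
G_temporal_inf,gyral,3.20
G_temporal_middle,gyral,3.27
S_calcarine,sulcal,2.19
S_central,sulcal,2.09
S_cingul-Marginalis,sulcal,2.48
S_circular_insula_ant,sulcal,3.17
S_circular_insula_inf,sulcal,2.80
S_circular_insula_sup,sulcal,2.91
S_collat_transv_ant,sulcal,2.88
S_collat_transv_post,sulcal,2.33
S_front_inf,sulcal,2.61
S_front_middle,sulcal,2.57
S_front_sup,sulcal,2.73
S_interm_prim-Jensen,sulcal,2.61
S_intrapariet_and_P_trans,sulcal,2.46
S_oc_middle_and_Lunatus,sulcal,2.34
S_oc_sup_and_transversal,sulcal,2.41
S_occipital_ant,sulcal,2.63
S_oc-temp_lat,sulcal,2.79
S_oc-temp_med_and_Lingual,sulcal,2.60
S_orbital_lateral,sulcal,2.50
S_orbital_med-olfact,sulcal,2.49
S_orbital-H_Shaped,sulcal,2.85
S_parieto_occipital,sulcal,2.45
S_pericallosal,sulcal,1.83
S_postcentral,sulcal,2.39
S_precentral-inf-part,sulcal,2.69
S_precentral-sup-part,sulcal,2.62
S_suborbital,sulcal,2.83
S_subparietal,sulcal,2.68
S_temporal_inf,sulcal,2.82
S_temporal_sup,sulcal,2.78
S_temporal_transverse,sulcal,2.75
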