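subnetwork,edge,p_ms_vs_hc,p_nmosd_vs_hc,p_ms_vs_nmosd
1,Hippocampus_L-ParaHippocampal_L,0.0120,0.3675,0.1476
1,Hippocampus_L-Fusiform_L,0.0016,0.4264,0.0016
1,Hippocampus_L-Temporal_Pole_Mid_L,0.0003,0.0809,0.6019
1,Hippocampus_L-Temporal_Inf_L,0.0003,0.0027,0.1291
1,ParaHippocampal_L-Fusiform_L,0.0117,0.4330,0.0648
1,Amygdala_L-Fusiform_L,0.0006,0.3211,0.0023
1,Amygdala_L-Temporal_Inf_L,0.0006,0.1159,0.0960
1,Fusiform_L-Temporal_Inf_L,0.0009,0.0944,0.0944
1,Lingual_L-Temporal_Inf_L,0.0015,0.0156,0.5481
1,Angular_L-Temporal_Mid_L,0.0042,0.0156,0.8146
1,Thalamus_L-Temporal_Inf_L,0.0009,0.0943,0.1657
1,Temporal_Sup_L-Temporal_Inf_L,0.0108,0.5087,0.0330
1,Temporal_Mid_L-Temporal_Inf_L,0.0003,0.0036,0.3916
1,Angular_L-Temporal_Mid_L,0.0042,0.0156,0.8146
1,Temporal_Pole_Sup_L-Temporal_Mid_L,0.0132,0.0149,0.8908
1,Parietal_Sup_L-Precuneus_L,0.0027,0.0248,0.8553
1,Parietal_Sup_L-Precuneus_R,0.0060,0.1915,0.1915
1,Precuneus_L-Precuneus_R,0.0045,0.0075,0.6966
1,Precuneus_R-Paracentral_Lobule_R,0.0144,0.2193,0.0335
1,Cuneus_R-Precuneus_R,0.0060,0.1610,0.3292
1,Occipital_Sup_R-Precuneus_L,0.0015,0.0024,0.1714
1,Occipital_Sup_R-Precuneus_R,0.0629,0.4413,0.0629
1,Calcarine_L-Cuneus_L,0.0138,0.0360,0.6150
1,Calcarine_R-Occipital_Sup_L,0.0003,0.0362,0.5915
1,Cuneus_L-Occipital_Sup_L,0.0015,0.2552,0.1632
1,Cuneus_L-Occipital_Sup_R,0.0183,0.0928,0.1210
1,Occipital_Sup_L-Occipital_Mid_L,0.0030,0.1429,0.3463
1,Occipital_Mid_L-Fusiform_L,0.0057,0.0121,0.9828
1,Occipital_Mid_L-Temporal_Inf_L,0.0045,0.0060,0.7591
2,Hippocampus_R-ParaHippocampal_R,0.0189,0.9795,0.0189
2,Hippocampus_R-Fusiform_R,0.0033,0.9492,0.0006
2,Hippocampus_R-Thalamus_R,0.0021,0.0546,0.5244
2,ParaHippocampal_R-Fusiform_R,0.0120,0.7685,0.0120
2,ParaHippocampal_R-Thalamus_R,0.0243,0.9313,0.0440
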