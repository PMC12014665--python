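study_label,n_f,n_m,mean_f,mean_m,sd_f,sd_m,presentations,stimulus_group
synthA_ac,20,18,10.8,11.9,2.6,2.9,200.0,air-conducted
synthB_ac,15,15,11.5,11.2,3.1,2.8,200.0,air-conducted
synthC_ac,34,36,10.2,10.9,2.2,2.5,512.0,air-conducted
synthD_bc,24,24,10.0,12.4,2.7,2.5,3044.0,body-conducted
synthE_bc,12,12,11.1,12.0,3.4,3.0,1500.0,body-conducted
synthF_ac,40,38,11.3,11.6,2.9,3.2,800.0,air-conducted
synthG_oth,16,14,10.6,11.1,2.4,2.2,,other
synthH_ac,22,20,11.0,10.7,2.8,3.0,256.0,air-conducted
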