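pollutant,study_id,beta,se,units
pm25,synthetic_study_A,0.00090,0.00030,ug/m3
pm25,synthetic_study_B,0.00070,0.00025,ug/m3
pm25,synthetic_study_C,0.00110,0.00040,ug/m3
o3,synthetic_study_D,0.00050,0.00020,ppb
o3,synthetic_study_E,0.00035,0.00015,ppb
o3,synthetic_study_F,0.00060,0.00030,ppb
no2,synthetic_study_G,0.00040,0.00020,ppb
no2,synthetic_study_H,0.00055,0.00025,ppb
no2,synthetic_study_I,0.00030,0.00015,ppb
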