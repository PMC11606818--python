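sample_id,arsenic_leaves_ug_per_kg,arsenic_infusion_ug_per_L,arsenic_transfer_pct,cadmium_leaves_ug_per_kg,cadmium_infusion_ug_per_L,cadmium_transfer_pct,lead_leaves_ug_per_kg,lead_infusion_ug_per_L,lead_transfer_pct
1,0.3,0.02,6.67,3.3,0.17,5.15,5.22,1.94,37.16
2,0.75,0.08,10.67,2.5,0.28,11.20,5.23,5,95.60
3,0.45,0.04,8.89,3.4,0.25,7.35,5.45,3.37,61.83
4,1.6,0.6,37.50,3.8,0.2,5.26,5.46,2.6,47.62
5,0.3,0.04,13.33,3.8,0.3,7.90,4.56,4,87.72
6,0.5,0.06,12,4.3,0.4,9.30,4.6,3.3,71.74
7,0,0,0,4.8,0.4,8.33,4,3.45,86.25
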