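sample_id,arsenic_leaves_ug_per_kg,arsenic_infusion_ug_per_L,arsenic_transfer_pct,cadmium_leaves_ug_per_kg,cadmium_infusion_ug_per_L,cadmium_transfer_pct,lead_leaves_ug_per_kg,lead_infusion_ug_per_L,lead_transfer_pct
1,2.1,0.57,27.14,3.1,1.11,35.81,5.53,3.45,62.39
2,1.9,0.11,5.79,3.2,1.45,45.31,4.17,3.37,80.81
3,2.1,0.22,10.48,4.4,0.12,2.73,4.11,3.08,74.94
4,1.02,0.02,1.96,3.3,0.02,0.61,4.56,3.63,79.60
5,1.02,0.02,1.96,3.8,0.05,1.32,6.14,3.15,51.30
6,1.03,0.03,2.91,3.6,0.08,2.22,4.32,2.29,53.01
7,1.39,0.39,28.06,4.3,0.07,1.63,4.23,3.34,78.96
8,1.06,0.06,5.66,4.5,0.08,1.78,4.21,2.42,57.48
9,1.09,0.09,8.26,2.9,0.11,3.79,4.21,2.11,50.12
10,1.11,0.11,9.91,4.3,0.09,2.09,4.37,3.32,75.97
11,1.34,0.34,25.37,3.5,0.03,0.86,7.34,6.02,82.02
12,1.44,0.44,30.56,3.3,0.02,0.61,4.49,1.42,31.63
13,1.3,0.3,23.08,2.4,0.06,2.50,5.68,2.56,45.07
14,1.52,0.52,34.21,3.4,0.11,3.23,3.67,1.86,50.68
15,1.48,0.48,32.43,3.3,0.09,2.73,5.32,1.42,26.69
16,1.05,0.05,4.76,3.6,1.06,29.44,4.81,1.91,39.71
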