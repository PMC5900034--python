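# Urine metabolite annotation windows (ppm) for collapsing per-variable
# ANOVA results to metabolites. One row per resonance window; metabolites
# may own several windows. Windows are +/- 0.015 ppm around standard
# urine assignments; unknowns (U1-U13) are bare windows.
metabolite	window_start_ppm	window_end_ppm
acetate	1.905	1.935
alanine	1.465	1.495
glycine	3.545	3.575
ascorbate	4.505	4.535
isovalerate	0.905	0.935
lactate	1.325	1.355
3-methyl-2-oxovalerate	1.085	1.115
butyrylglycine	0.915	0.945
butyrylglycine	1.605	1.635
cinnamoylglycine	6.715	6.745
hexanoylglycine	0.865	0.895
6H6MH3O	1.002	1.032
6H6MH3O	1.194	1.224
6H6MH3O	1.725	1.755
arabinose	4.515	4.545
D-xylose	4.575	4.605
D-xylose	5.195	5.225
D-glucose	4.645	4.675
D-glucuronate	4.635	4.665
fucose	1.235	1.265
2-oxoglutarate	2.435	2.465
2-oxoglutarate	2.995	3.025
citrate	2.545	2.575
citrate	2.685	2.715
succinate	2.395	2.425
1-methylnicotinamide	4.455	4.485
allantoin	5.385	5.415
dimethylamine	2.715	2.745
creatinine	3.025	3.055
creatinine	4.035	4.065
putrescine	1.765	1.795
taurine	3.255	3.285
taurine	3.418	3.448
trimethylamine	2.865	2.895
trimethylamine-N-oxide	3.255	3.285
trigonelline	4.425	4.455
ureidopropionate	2.365	2.395
ureidopropionate	3.295	3.325
hippurate	7.545	7.575
hippurate	7.625	7.655
hippurate	7.825	7.855
indoxylsulphate	7.495	7.525
indoxylsulphate	7.695	7.725
4-cresol-glucuronide	2.285	2.315
4-cresol-glucuronide	5.065	5.095
4-cresol-sulphate	2.335	2.365
phenylacetylglycine	7.355	7.385
phenylacetylglycine	7.415	7.445
U1	1.213	1.243
U2	1.295	1.325
U3	1.815	1.845
U4	2.049	2.079
U5	2.167	2.197
U6	2.725	2.755
U7	2.765	2.795
U8	4.395	4.425
U9	4.560	4.590
U10	4.975	5.005
U11	5.069	5.099
U12	5.075	5.105
U13	8.045	8.075
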