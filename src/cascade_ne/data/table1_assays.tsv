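# Clotting-assay results and published NE decreases for the fourteen
# validation compounds.  delta_* are (sample time - vehicle control time) /
# vehicle control time for the aPTT, PT and TT assays; printed_sum is the
# published sum-of-ratios column, retained verbatim (in five rows it
# differs by 0.001 from the sum of the published components, a rounding
# artifact of the source table); ne_decrease is the published decrease of
# network efficiency computed from the authors' multi-target docking runs.
compound	delta_aptt	delta_pt	delta_tt	printed_sum	ne_decrease
salvianolic_acid_a	0.121	0.175	0.296	0.592	11.78
salvianolic_acid_b	0.375	0.132	0.265	0.771	11.97
rutin	0.057	0	0.783	0.84	12.69
quercetin	0	0.122	0.455	0.577	11.48
liensinine	0.206	0	0.113	0.319	11.42
fangchinoline	0.215	0.022	0.161	0.398	11.62
folic_acid	0.268	0.007	0.167	0.442	10.96
l_glutamine	0.068	0.098	0.035	0.2	8.74
argatroban_intermediate_1	0.384	0.065	0.112	0.56	10.63
argatroban_intermediate_2	0.368	0.049	0.182	0.599	10.26
argatroban_intermediate_3	0.243	0.081	0.126	0.45	11.47
argatroban_intermediate_4	0.305	0.138	0.161	0.604	11.94
argatroban_intermediate_5	0.167	0.033	0.196	0.395	10.9
argatroban_intermediate_6	0.294	0.122	0.231	0.648	12.05
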