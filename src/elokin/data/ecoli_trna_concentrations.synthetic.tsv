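# SYNTHETIC total tRNA, active-ribosome and EF-Tu concentrations (uM) for
# four specific growth rates (columns, h^-1). Relative tRNA abundances and
# pool totals are plausible magnitudes, not measurements; the same relative
# composition is used at every growth rate.
name	0.7	1.07	1.6	2.5
Ala1B	10.0293	12.5366	15.0440	18.0528
Ala2	1.9133	2.3916	2.8699	3.4439
Arg2	14.6582	18.3228	21.9873	26.3848
Arg3	1.9750	2.4688	2.9625	3.5550
Arg4	2.7156	3.3945	4.0734	4.8881
Arg5	1.2961	1.6201	1.9441	2.3330
Asn	3.7031	4.6289	5.5547	6.6656
Asp1	7.4063	9.2578	11.1094	13.3313
Cys	4.9067	6.1333	7.3600	8.8320
Gln1	2.3453	2.9316	3.5180	4.2216
Gln2	2.7156	3.3945	4.0734	4.8881
Glu2	14.5657	18.2071	21.8485	26.2182
Gly1	3.3020	4.1274	4.9529	5.9435
Gly2	3.3020	4.1274	4.9529	5.9435
Gly3	13.4547	16.8184	20.1821	24.2185
His	1.9750	2.4688	2.9625	3.5550
Ile1	5.3695	6.7119	8.0543	9.6652
Ile2	3.3945	4.2432	5.0918	6.1102
Leu1	13.7942	17.2427	20.6913	24.8295
Leu2	2.9316	3.6646	4.3975	5.2770
Leu3	2.0676	2.5845	3.1014	3.7216
Leu4	5.8942	7.3677	8.8412	10.6095
Leu5	3.2402	4.0503	4.8604	5.8324
Lys	5.9250	7.4063	8.8875	10.6650
Met	7.2520	9.0650	10.8780	13.0535
Phe	4.8758	6.0947	7.3137	8.7764
Pro1	2.7773	3.4717	4.1660	4.9992
Pro2	2.2219	2.7773	3.3328	3.9994
Pro3	1.7898	2.2373	2.6848	3.2217
Ser1	4.0117	5.0147	6.0176	7.2211
Ser2	1.0492	1.3115	1.5738	1.8886
Ser3	4.8758	6.0947	7.3137	8.7764
Ser5	2.0059	2.5073	3.0088	3.6106
Thr1	3.3945	4.2432	5.0918	6.1102
Thr2	1.7281	2.1602	2.5922	3.1106
Thr3	3.3945	4.2432	5.0918	6.1102
Thr4	2.8391	3.5488	4.2586	5.1103
Trp	2.9008	3.6260	4.3512	5.2214
Tyr1	2.3762	2.9702	3.5643	4.2771
Tyr2	3.8883	4.8604	5.8324	6.9989
Val1	11.8500	14.8125	17.7750	21.3300
Val2A	1.9441	2.4302	2.9162	3.4995
Val2B	1.9441	2.4302	2.9162	3.4995
ribosomes_active	17.0	24.0	32.0	45.0
EF-Tu_total	161.5	204.0	240.0	292.5
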