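# SYNTHETIC codon usages in percent per growth rate (columns, h^-1).
# Baseline is a genome-wide-style E. coli usage; the 2.5 h^-1 column is
# reweighted so AAA usage is 4.67% (transcriptome-weighted-style), all other
# ratios preserved. Stop codons excluded.
codon	0.7	1.07	1.6	2.5
UUU	2.2278	2.2278	2.2278	2.1979
UUC	1.6658	1.6658	1.6658	1.6434
UUA	1.3949	1.3949	1.3949	1.3761
UUG	1.3748	1.3748	1.3748	1.3563
UCU	0.8530	0.8530	0.8530	0.8415
UCC	0.8630	0.8630	0.8630	0.8514
UCA	0.7225	0.7225	0.7225	0.7128
UCG	0.8931	0.8931	0.8931	0.8811
UAU	1.6257	1.6257	1.6257	1.6038
UAC	1.2243	1.2243	1.2243	1.2078
UGU	0.5218	0.5218	0.5218	0.5148
UGC	0.6422	0.6422	0.6422	0.6336
UGG	1.5253	1.5253	1.5253	1.5048
CUU	1.1039	1.1039	1.1039	1.0890
CUC	1.1039	1.1039	1.1039	1.0890
CUA	0.3914	0.3914	0.3914	0.3861
CUG	5.2785	5.2785	5.2785	5.2076
CCU	0.7025	0.7025	0.7025	0.6930
CCC	0.5519	0.5519	0.5519	0.5445
CCA	0.8430	0.8430	0.8430	0.8316
CCG	2.3281	2.3281	2.3281	2.2969
CAU	1.2945	1.2945	1.2945	1.2771
CAC	0.9734	0.9734	0.9734	0.9603
CAA	1.5354	1.5354	1.5354	1.5147
CAG	2.8901	2.8901	2.8901	2.8513
CGU	2.0973	2.0973	2.0973	2.0692
CGC	2.2077	2.2077	2.2077	2.1781
CGA	0.3613	0.3613	0.3613	0.3564
CGG	0.5419	0.5419	0.5419	0.5346
AUU	3.0406	3.0406	3.0406	2.9998
AUC	2.5188	2.5188	2.5188	2.4850
AUA	0.4415	0.4415	0.4415	0.4356
AUG	2.7998	2.7998	2.7998	2.7622
ACU	0.9032	0.9032	0.9032	0.8910
ACC	2.3482	2.3482	2.3482	2.3167
ACA	0.7125	0.7125	0.7125	0.7029
ACG	1.4451	1.4451	1.4451	1.4256
AAU	1.7762	1.7762	1.7762	1.7524
AAC	2.1776	2.1776	2.1776	2.1484
AAA	3.3718	3.3718	3.3718	4.6700
AAG	1.0336	1.0336	1.0336	1.0197
AGU	0.8831	0.8831	0.8831	0.8712
AGC	1.6157	1.6157	1.6157	1.5939
AGA	0.2107	0.2107	0.2107	0.2079
AGG	0.1204	0.1204	0.1204	0.1188
GUU	1.8364	1.8364	1.8364	1.8118
GUC	1.5354	1.5354	1.5354	1.5147
GUA	1.0938	1.0938	1.0938	1.0791
GUG	2.6493	2.6493	2.6493	2.6137
GCU	1.5354	1.5354	1.5354	1.5147
GCC	2.5590	2.5590	2.5590	2.5246
GCA	2.0171	2.0171	2.0171	1.9900
GCG	3.3919	3.3919	3.3919	3.3463
GAU	3.2213	3.2213	3.2213	3.1780
GAC	1.9167	1.9167	1.9167	1.8910
GAA	3.9538	3.9538	3.9538	3.9007
GAG	1.7863	1.7863	1.7863	1.7623
GGU	2.4787	2.4787	2.4787	2.4454
GGC	2.9704	2.9704	2.9704	2.9305
GGA	0.8028	0.8028	0.8028	0.7920
GGG	1.1139	1.1139	1.1139	1.0989
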