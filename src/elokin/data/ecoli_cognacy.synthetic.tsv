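# SYNTHETIC reconstruction of the E. coli codon-tRNA cognacy classification.
# Cognate assignments follow standard E. coli decoding (43 elongator species,
# Dong-style species names); near-cognate = non-cognate tRNA whose cognate
# codon set contains a codon at Hamming distance 1 from the row codon.
# NOT measured reference data; ambiguous wobble readings resolved as listed
# in the generating script.
codon	Ala1B	Ala2	Arg2	Arg3	Arg4	Arg5	Asn	Asp1	Cys	Gln1	Gln2	Glu2	Gly1	Gly2	Gly3	His	Ile1	Ile2	Leu1	Leu2	Leu3	Leu4	Leu5	Lys	Met	Phe	Pro1	Pro2	Pro3	Ser1	Ser2	Ser3	Ser5	Thr1	Thr2	Thr3	Thr4	Trp	Tyr1	Tyr2	Val1	Val2A	Val2B
UUU	-	-	-	-	-	-	-	-	N	-	-	-	-	-	-	-	N	-	-	N	N	N	N	-	-	C	-	-	-	N	-	-	N	-	-	-	-	-	N	N	N	N	N
UUC	-	-	-	-	-	-	-	-	N	-	-	-	-	-	-	-	N	-	-	N	-	N	N	-	-	C	-	-	-	-	-	-	N	-	-	-	-	-	N	N	-	N	N
UUA	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	-	-	N	N	C	-	-	N	-	-	-	N	-	-	-	-	-	-	-	-	-	-	N	-	-
UUG	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	-	N	C	C	-	N	N	-	-	-	N	N	-	-	-	-	-	-	N	-	-	N	-	-
UCU	N	N	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	-	N	N	C	N	-	C	N	-	N	N	-	N	N	-	-	-
UCC	-	N	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	-	N	-	N	N	-	C	N	-	N	-	-	N	N	-	-	-
UCA	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	-	-	-	-	-	N	C	N	-	N	-	-	-	N	-	-	-	-	-	-
UCG	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	N	-	-	-	N	-	N	C	C	-	N	-	N	-	-	N	-	-	-	-	-
UAU	-	-	-	-	-	-	N	N	N	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	N	-	-	-	N	-	-	N	-	-	-	-	-	C	C	-	-	-
UAC	-	-	-	-	-	-	N	N	N	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	N	-	-	-	-	-	-	N	-	-	-	-	-	C	C	-	-	-
UGU	-	-	N	-	-	-	-	-	C	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	N	-	-	-	N	-	N	N	-	-	-	-	N	N	N	-	-	-
UGC	-	-	N	-	-	-	-	-	C	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	N	-	-	-	-	-	N	N	-	-	-	-	N	N	N	-	-	-
UGG	-	-	-	N	-	N	-	-	N	-	-	-	N	N	-	-	-	-	-	-	-	N	N	-	-	-	-	-	-	N	N	-	-	-	-	-	-	C	-	-	-	-	-
CUU	-	-	N	-	-	-	-	-	-	-	-	-	-	-	-	N	N	-	N	C	C	-	-	-	-	N	-	N	N	-	-	-	-	-	-	-	-	-	-	-	N	N	N
CUC	-	-	N	-	-	-	-	-	-	-	-	-	-	-	-	N	N	-	N	C	N	-	-	-	-	N	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	N	N
CUA	-	-	N	-	-	-	-	-	-	N	-	-	-	-	-	-	-	N	N	N	C	-	N	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	-	N	-	-
CUG	-	-	-	N	-	-	-	-	-	-	N	-	-	-	-	-	-	-	C	N	C	N	N	-	N	-	N	-	N	-	-	-	-	-	-	-	-	-	-	-	N	-	-
CCU	N	N	N	-	-	-	-	-	-	-	-	-	-	-	-	N	-	-	-	N	N	-	-	-	-	-	N	C	C	N	-	-	N	N	-	N	N	-	-	-	-	-	-
CCC	-	N	N	-	-	-	-	-	-	-	-	-	-	-	-	N	-	-	-	N	-	-	-	-	-	-	N	C	N	-	-	-	N	N	-	N	-	-	-	-	-	-	-
CCA	N	-	N	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	N	-	-	-	-	-	N	N	C	N	-	-	-	-	-	-	N	-	-	-	-	-	-
CCG	N	-	-	N	-	-	-	-	-	-	N	-	-	-	-	-	-	-	N	-	N	-	-	-	-	-	C	N	C	N	N	-	-	-	N	-	-	-	-	-	-	-	-
CAU	-	-	N	-	-	-	N	N	-	N	N	-	-	-	-	C	-	-	-	N	N	-	-	-	-	-	-	N	N	-	-	-	-	-	-	-	-	-	N	N	-	-	-
CAC	-	-	N	-	-	-	N	N	-	N	N	-	-	-	-	C	-	-	-	N	-	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	N	N	-	-	-
CAA	-	-	N	-	-	-	-	-	-	C	N	N	-	-	-	N	-	-	-	-	N	-	-	N	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-
CAG	-	-	-	N	-	-	-	-	-	N	C	N	-	-	-	N	-	-	N	-	N	-	-	N	-	-	N	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-
CGU	-	-	C	N	-	-	-	-	N	-	-	-	-	-	N	N	-	-	-	N	N	-	-	-	-	-	-	N	N	-	-	N	-	-	-	-	-	-	-	-	-	-	-
CGC	-	-	C	N	-	-	-	-	N	-	-	-	-	-	N	N	-	-	-	N	-	-	-	-	-	-	-	N	-	-	-	N	-	-	-	-	-	-	-	-	-	-	-
CGA	-	-	C	N	N	-	-	-	-	N	-	-	-	N	-	-	-	-	-	-	N	-	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-
CGG	-	-	N	C	-	N	-	-	-	-	N	-	N	N	-	-	-	-	N	-	N	-	-	-	-	-	N	-	N	-	-	-	-	-	-	-	-	N	-	-	-	-	-
AUU	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	C	N	-	N	N	-	-	-	N	N	-	-	-	-	-	N	-	N	-	N	N	-	-	-	N	N	N
AUC	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	C	N	-	N	-	-	-	-	N	N	-	-	-	-	-	N	-	N	-	N	-	-	-	-	-	N	N
AUA	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	-	N	C	-	-	N	-	N	N	N	-	-	-	-	-	-	-	-	-	-	-	N	-	-	-	N	-	-
AUG	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	N	N	N	-	N	N	N	N	C	-	-	-	-	-	-	-	-	-	N	-	-	-	-	-	N	-	-
ACU	N	N	-	-	-	-	N	-	-	-	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	N	N	N	-	N	N	C	N	C	C	-	-	-	-	-	-
ACC	-	N	-	-	-	-	N	-	-	-	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	N	-	-	-	N	N	C	N	C	N	-	-	-	-	-	-
ACA	N	-	-	-	N	-	-	-	-	-	-	-	-	-	-	-	-	N	-	-	-	-	-	N	-	-	-	-	N	N	-	-	-	N	N	N	C	-	-	-	-	-	-
ACG	N	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	N	-	N	-	N	N	N	-	-	N	C	N	N	-	-	-	-	-	-
AAU	-	-	-	-	-	-	C	N	-	-	-	-	-	-	-	N	N	-	-	-	-	-	-	N	-	-	-	-	-	-	-	N	-	N	-	N	N	-	N	N	-	-	-
AAC	-	-	-	-	-	-	C	N	-	-	-	-	-	-	-	N	N	-	-	-	-	-	-	N	-	-	-	-	-	-	-	N	-	N	-	N	-	-	N	N	-	-	-
AAA	-	-	-	-	N	-	N	-	-	N	-	N	-	-	-	-	-	N	-	-	-	-	-	C	-	-	-	-	-	-	-	-	-	-	-	-	N	-	-	-	-	-	-
AAG	-	-	-	-	-	N	N	-	-	-	N	N	-	-	-	-	-	-	-	-	-	-	-	C	N	-	-	-	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-
AGU	-	-	N	-	N	N	N	-	N	-	-	-	-	-	N	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	C	-	N	-	N	N	-	-	-	-	-	-
AGC	-	-	N	-	N	N	N	-	N	-	-	-	-	-	N	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	C	-	N	-	N	-	-	-	-	-	-	-
AGA	-	-	N	-	C	N	-	-	-	-	-	-	-	N	-	-	-	N	-	-	-	-	-	N	-	-	-	-	-	-	-	N	-	-	-	-	N	-	-	-	-	-	-
AGG	-	-	-	N	N	C	-	-	-	-	-	-	N	N	-	-	-	-	-	-	-	-	-	N	N	-	-	-	-	-	-	N	-	-	N	-	-	N	-	-	-	-	-
GUU	N	N	-	-	-	-	-	N	-	-	-	-	-	-	N	-	N	-	-	N	N	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	C	C	C
GUC	-	N	-	-	-	-	-	N	-	-	-	-	-	-	N	-	N	-	-	N	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	C	C
GUA	N	-	-	-	-	-	-	-	-	-	-	N	-	N	-	-	-	N	-	-	N	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	C	N	N
GUG	N	-	-	-	-	-	-	-	-	-	-	N	N	N	-	-	-	-	N	-	N	N	N	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	C	N	N
GCU	C	C	-	-	-	-	-	N	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	-	-	N	N	N	-	-	N	N	-	N	N	-	-	-	N	N	N
GCC	N	C	-	-	-	-	-	N	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	-	-	N	-	-	-	-	N	N	-	N	-	-	-	-	-	N	N
GCA	C	N	-	-	-	-	-	-	-	-	-	N	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	N	-	-	-	-	-	-	N	-	-	-	N	-	-
GCG	C	N	-	-	-	-	-	-	-	-	-	N	N	N	-	-	-	-	-	-	-	-	-	-	-	-	N	-	N	N	N	-	-	-	N	-	-	-	-	-	N	-	-
GAU	N	N	-	-	-	-	N	C	-	-	-	N	-	-	N	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	N	N	N	N
GAC	-	N	-	-	-	-	N	C	-	-	-	N	-	-	N	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	N	-	N	N
GAA	N	-	-	-	-	-	-	N	-	N	-	C	-	N	-	-	-	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	-	-
GAG	N	-	-	-	-	-	-	N	-	-	N	C	N	N	-	-	-	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	-	-
GGU	N	N	N	-	-	-	-	N	N	-	-	-	N	N	C	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	N	N	N
GGC	-	N	N	-	-	-	-	N	N	-	-	-	N	N	C	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	-	-	-	-	-	-	-	-	-	N	N
GGA	N	-	N	-	N	-	-	-	-	-	-	N	N	C	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	-	-
GGG	N	-	-	N	-	N	-	-	-	-	-	N	C	C	N	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	N	-	-	N	-	-
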