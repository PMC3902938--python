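# S. cerevisiae nuclear tRNA gene copy numbers by anticodon (RNA space).
# Reconstructed from the genomic tRNA database census commonly used for
# tRNA adaptation index calculations; counts are approximate and intended
# as a self-contained default, replaceable by the user.
anticodon	gene_copy_number
AGC	11
UGC	5
ACG	6
CCG	1
UCU	11
CCU	1
GUU	10
GUC	16
GCA	4
UUG	9
CUG	1
UUC	14
CUC	2
GCC	16
UCC	3
CCC	2
GUG	7
AAU	13
UAU	2
UAA	7
CAA	10
UAG	3
GAG	1
CUU	14
UUU	7
CAU	5
GAA	10
AGG	2
UGG	10
AGA	11
CGA	1
UGA	3
GCU	4
AGU	11
CGU	1
UGU	4
CCA	6
GUA	8
AAC	14
UAC	2
CAC	2
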