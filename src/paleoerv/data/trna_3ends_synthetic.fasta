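>tRNA-Pro synthetic representative 3' 18-mer (CCA tail)
GGGTCGTGGCGCAGTCCA
>tRNA-Lys synthetic representative 3' 18-mer (CCA tail)
TCCCTGTTCGGGCGCCCA
>tRNA-Gly synthetic representative 3' 18-mer (CCA tail)
CATTGGTGCGATTCTCCA
>tRNA-Leu synthetic representative 3' 18-mer (CCA tail)
AGGACTGTAAATCCTCCA
>tRNA-Arg synthetic representative 3' 18-mer (CCA tail)
CGCCTGATTAGCGATCCA
>tRNA-Ser synthetic representative 3' 18-mer (CCA tail)
GAGGTTCGAATCCTTCCA
>tRNA-Trp synthetic representative 3' 18-mer (CCA tail)
ACACGGGATTTGAACCCA
>tRNA-Phe synthetic representative 3' 18-mer (CCA tail)
TGGTGCGAATTCTGTCCA
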