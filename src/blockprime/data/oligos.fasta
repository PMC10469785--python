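>1389F 18S V9 amplification forward primer
ACACTCTTTCCCTACACGACGCTCTTCCGATCTTTGTACACACCGCCC
>1015R 18S V9 amplification reverse primer
ACACTCTTTCCCTACACGACGCTCTTCCGATCTCCTTCYGCAGGTTCACCTAC
>341F 16S V3-V4 amplification forward primer
ACACTCTTTCCCTACACGACGCTCTTCCGATCTCCTACGGGRSGCAGCAG
>785R 16S V3-V4 amplification reverse primer
ACACTCTTTCCCTACACGACGCTCTTCCGATCTGACTACHVGGGTATCTAATCC
>BP-F_Hi_V9 Hermetia illucens 18S V9 blocking primer [SpcC3]
ATTTAGTGAGGTCTCCGGACGTG
>BP-R_Hi_V9 Hermetia illucens 18S V9 blocking primer [SpcC3]
GGTCAACTTTTGCGAAACAACC
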