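name	role	adapter_tail	terminator
1389F	amplification_forward	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	none
1015R	amplification_reverse	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	none
341F	amplification_forward	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	none
785R	amplification_reverse	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	none
BP-F_Hi_V9	blocking		C3_spacer
BP-R_Hi_V9	blocking		C3_spacer
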