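# Default bit values per kind of metabolite-identification evidence for
# MICE (metabolite identification carbon efficiency) scoring: one bit per
# independently matched item of identification information. Overridable;
# the authoritative rubric is the MICE methodology itself — these defaults
# only say that each matched item counts once.
kind	bits_per_item
1H_shift	1
13C_shift	1
multiplicity	1
J_coupling	1
HSQC_correlation	1
HMBC_correlation	1
TOCSY_COSY_correlation	1
spike_in	1
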