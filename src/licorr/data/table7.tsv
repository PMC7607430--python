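enzyme	substrate	product	constraint
b4GalT	(GN	(Ab4GN	*...GNb2|Ma3 or*...GNb4|Ma3 or*...GNb2|Ma6 or*...GNb6|Ma6
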