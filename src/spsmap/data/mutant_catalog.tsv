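protein	label	site	phenotype
Ssy1	T382K	382	gain_of_function
Ssy1	V694F	694	gain_of_function
Ssy1	F333S	333	gain_of_function
Ssy1	S351T	351	gain_of_function
Ssy1	V354L	354	gain_of_function
Ssy1	F358L	358	gain_of_function
Ssy1	G790V	790	gain_of_function
Ssy1	T639I	639	hypo_responsive
Ptr3	T435K	435	gain_of_function
Ptr3	Q439R	439	gain_of_function
Ptr3	E522K	522	loss_of_function
Ptr3	T525A	525	loss_of_function
Ssy5	E131K	131	gain_of_function
Ssy5	F575V	575	gain_of_function
Ssy5	Q576P	576	gain_of_function
Ssy5		126	gain_of_function
Ssy5		129	gain_of_function
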