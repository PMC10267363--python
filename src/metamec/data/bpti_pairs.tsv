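group	donor_resnum	donor_atom	acceptor_resnum	acceptor_atom
beta	35	N	18	O
beta	18	N	35	O
beta	33	N	20	O
beta	20	N	33	O
beta	31	N	22	O
beta	22	N	31	O
beta	29	N	24	O
beta	24	N	29	O
alpha1	5	N	2	O
alpha1	6	N	3	O
alpha1	7	N	4	O
alpha2	52	N	48	O
alpha2	53	N	49	O
alpha2	54	N	50	O
alpha2	54	N	51	O
alpha2	55	N	51	O
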