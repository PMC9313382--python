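chr1	117200000	120400000	del1p_1p12	loss
chr1	92800000	94300000	del1p_1p22_1	loss
chr1	50200000	55600000	del1p_1p32_3	loss
chr1	143200000	155100000	gain1q21	gain
chr17	6500000	10800000	del17p	loss
chr13	45800000	53400000	del13q	loss
chr14	89300000	107043718	del14q	loss
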