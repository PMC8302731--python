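# factor: SRSF1 (SF2/ASF)
# source: ESEfinder 3.0 SELEX score matrix, transcribed from Cartegni et al. 2003, Nucleic Acids Res 31:3568 (matrix) and Smith et al. 2006, Hum Mol Genet 15:2490 (3.0 thresholds)
# threshold: 1.956
pos	A	C	G	U
1	-1.14	1.37	-0.21	-1.58
2	0.62	-1.10	0.17	-0.50
3	-1.58	0.73	0.48	-1.58
4	1.32	0.33	-1.58	-1.13
5	-1.58	0.94	0.33	-1.58
6	-1.58	-1.58	0.99	-1.13
7	0.62	-1.58	-0.11	0.27
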