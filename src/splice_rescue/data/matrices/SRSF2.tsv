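# factor: SRSF2 (SC35)
# source: ESEfinder 3.0 SELEX score matrix, transcribed from Cartegni et al. 2003, Nucleic Acids Res 31:3568 (matrix) and Smith et al. 2006, Hum Mol Genet 15:2490 (3.0 thresholds)
# threshold: 2.383
pos	A	C	G	U
1	-0.88	-1.16	0.86	-1.18
2	-1.16	0.87	-1.58	0.32
3	0.73	-0.33	0.45	-0.98
4	-1.58	0.45	-1.58	1.12
5	0.72	-0.26	-1.58	0.24
6	-1.58	0.38	0.12	0.48
7	0.23	0.42	-0.20	-1.58
8	0.15	0.30	-0.36	0.38
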