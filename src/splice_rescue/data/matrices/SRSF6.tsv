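# factor: SRSF6 (SRp55)
# source: ESEfinder 3.0 SELEX score matrix, transcribed from Cartegni et al. 2003, Nucleic Acids Res 31:3568 (matrix) and Smith et al. 2006, Hum Mol Genet 15:2490 (3.0 thresholds)
# threshold: 2.676
pos	A	C	G	U
1	-0.66	0.39	-1.58	1.22
2	0.11	-1.58	0.72	-1.58
3	-0.66	1.48	-1.58	0.07
4	0.11	-1.58	0.72	0.23
5	-1.58	0.95	-1.58	0.72
6	0.61	-0.45	-0.45	-1.58
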