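# factor: SRSF5 (SRp40)
# source: ESEfinder 3.0 SELEX score matrix, transcribed from Cartegni et al. 2003, Nucleic Acids Res 31:3568 (matrix) and Smith et al. 2006, Hum Mol Genet 15:2490 (3.0 thresholds)
# threshold: 2.67
pos	A	C	G	U
1	-0.13	0.56	-1.58	0.92
2	-1.58	0.68	-0.14	-1.58
3	1.28	-1.58	0.26	-1.58
4	-0.33	1.24	-1.58	-1.58
5	0.97	-0.77	0.72	-1.58
6	-0.13	0.13	0.97	-1.58
7	-1.58	-0.05	-1.58	0.89
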