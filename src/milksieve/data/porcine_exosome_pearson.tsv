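# Pairwise Pearson correlations (r, two-sided p in brackets) among the
# plant-miRNA count profiles of six porcine breast-milk exosome samples:
# three collected at day 0 post partum and one each at days 14, 21 and 28.
# Upper triangle only; the matrix is symmetric with unit diagonal.
	Day0_S1	Day0_S2	Day0_S3	Day14	Day21	Day28
Day0_S1		0.205 (0.336)	0.126 (0.575)	0.262 (0.238)	0.185 (0.398)	0.654 (0.0002)
Day0_S2			0.004 (0.984)	0.099 (0.651)	0.131 (0.590)	0.349 (0.080)
Day0_S3				0.214 (0.378)	0.616 (0.006)	0.013 (0.952)
Day14					0.067 (0.769)	0.146 (0.494)
Day21						0.391 (0.048)
Day28
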