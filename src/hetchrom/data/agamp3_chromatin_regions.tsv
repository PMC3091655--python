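arm	class	start	end	gene_count	start_marker	end_marker	subclass
X	EU	1	19928574	1035	Telomere	AGAP001035
X	CH	20009764	24393108	56	AGAP001039	Centromere
2R	EU	1	58969802	3550	Telomere	AGAP004644
2R	CH	58984778	61545105	32	26D02	Centromere
2L	CH	1	2431617	31	Centromere	AGAP004707
2L	PEU	2487770	5042389	183	AGAP004711	AGAP004892
2L	IH	5078962	5788875	12	AAAB01008948_1	AGAP004905	d
2L	EU	6015228	49364325	2812	AGAP004919	Telomere
3R	EU	1	38815826	1960	Telomere	AGAP009690
3R	IH	38988757	41860198	35	AGAP009696	AGAP009730	c
3R	EU	41888356	52131026	554	BAC 30P16	BAC 25H11
3R	CH	52161877	53200684	23	AGAP010287	Centromere
3L	CH	1	1815119	33	Centromere	AGAP010342
3L	PEU	1896830	4235209	138	AGAP010344	AGAP010481
3L	IH	4264713	5031692	10	AGAP010482	AGAP010491
3L	EU	5133257	41963435	1923	AGAP010505	Telomere
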