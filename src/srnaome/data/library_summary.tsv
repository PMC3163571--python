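library	cultivar	tissue	condition	virus	reads	unique_sequences
Wtm	cv. Tendral	Cotyledon	Mock-inoculated	--	33123	15624
Wt	cv. Tendral	Cotyledon	Virus-infected	WMV-M116	35860	12840
Cwm	accession TGR-1551	Cotyledon	Mock-inoculated	--	41039	21122
Cw	accession TGR-1551	Cotyledon	Virus-infected	WMV-M116	36330	24100
15d	cv. Piel de Sapo	Fruit	Healthy, 15 days after pollination	--	21662	14620
45d	cv. Piel de Sapo	Fruit	Healthy, 45 days after pollination	--	9942	8167
c1	cv. Piel de Sapo	Ovary	Healthy	--	18764	15269
c5	cv. Piel de Sapo	Ovary	Healthy	--	14529	12608
Ta5	cv. Tendral	Cotyledon	Virus-infected	MNSV-alfa5	43170	22869
3'T	cv. Tendral	Cotyledon	Virus-infected	MNSV (chimeric)	56425	56425
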