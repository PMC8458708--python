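study_id	tumor_type	n	orr_pct	dcr_pct	year	phase	line	intervention
Motzer2021	RCC	355	71.0	90.2	2021	III	1L	lenvatinib+pembrolizumab
Chung2021	GC	31	10.0	48.0	2021	II	3L	lenvatinib+pembrolizumab
Villanueva2021	CHOL	31	10.0	68.0	2021	II	2L	lenvatinib+pembrolizumab
GomezRoca2021	COAD	32	22.0	47.0	2021	II	3L	lenvatinib+pembrolizumab
Lee2020	RCC	104	51.0	91.0	2020	II	>=2L	lenvatinib+pembrolizumab
Kawazoe2020	GC	29	69.0	100.0	2020	II	1/2L	lenvatinib+pembrolizumab
Haugen2020	THCA	30	62.0	97.0	2020	II	>=2L	lenvatinib+pembrolizumab
Makker2020	UCEC	94	38.3	78.7	2020	Ib/II	>=2L	lenvatinib+pembrolizumab
Taylor2020-SKCM	SKCM	21	48.0	81.0	2020	Ib/II	>=2L	lenvatinib+pembrolizumab
Arance2020	SKCM	103	21.4	65.0	2020	Ib/II	>=2L	lenvatinib+pembrolizumab
Finn2020	LIHC	104	46.0	88.0	2020	Ib	1L	lenvatinib+pembrolizumab
Li2020	LIHC	22	50.0	90.9	2020		1L	lenvatinib+PD-1 inhibitors
Kudo2020	LIHC	24	66.7	91.7	2020	Ib	1L	lenvatinib+nivolumab
Taylor2020-HNSC	HNSC	22	46.0	91.0	2020	Ib/II	>=2L	lenvatinib+pembrolizumab
Taylor2020-NSCLC	NSCLC	21	33.0	81.0	2020	Ib/II	>=2L	lenvatinib+pembrolizumab
Lwin2020-OV	OV	31	32.3	74.2	2020	II	4L	lenvatinib+pembrolizumab
Lwin2020-TNBC	TNBC	31	29.0	58.1	2020	II	2/3L	lenvatinib+pembrolizumab
Lin2020	CHOL	32	25.0	78.1	2020		>=2L	lenvatinib+pembrolizumab
Taylor2020-BLCA	BLCA	20	25.0	70.0	2020	Ib/II	>=2L	lenvatinib+pembrolizumab
Lwin2020-GBM	GBM	31	16.1	58.1	2020	II	2L	lenvatinib+pembrolizumab
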