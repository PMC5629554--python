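drug	cancer_abbreviation	n_trials
Thalidomide	Lymphoma	174
Temsirolimus	BRCA	129
Cetuximab	Lung cancer	77
Ofatumumab	Lymphoma	64
Erlotinib	HNC	62
Temsirolimus	PACA	50
Aldesleukin	Lymphoma	44
Obinutuzumab	Lymphoma	44
Gefitinib	HNC	43
Temsirolimus	BrainC	40
Axitinib	KNC	39
Cetuximab	PACA	31
Erlotinib	CRC	31
Panitumumab	HNC	31
Sorafenib	Melanoma	30
Vandetanib	Lung cancer	29
Erlotinib	BRCA	25
Sorafenib	PACA	25
Sorafenib	CRC	23
Trastuzumab	Lung cancer	22
Vandetanib	HNC	22
Carfilzomib	Lymphoma	20
Lapatinib	HNC	20
Afatinib	HNC	17
Sunitinib	Sarcoma	17
Panitumumab	Lung cancer	16
Sorafenib	Sarcoma	16
Sunitinib	Liver cancer	16
Cetuximab	BRCA	14
Peginterferon Alfa-2b	Leukemia	14
Sunitinib	CRC	14
Lapatinib	GCA	13
Gefitinib	CRC	12
Gefitinib	BRCA	12
Leuprolide	BRCA	12
Vandetanib	BRCA	11
Sorafenib	GCA	10
Bicalutamide	BRCA	9
Denileukin diftitox	Melanoma	9
Enzalutamide	BRCA	9
Ibritumomab tiuxetan	Leukemia	9
Cabozantinib	Lung cancer	8
Regorafenib	Liver cancer	8
Lapatinib	Lung cancer	7
Lapatinib	CRC	7
Panitumumab	PACA	7
Ramucirumab	Liver cancer	7
Vandetanib	CRC	7
Vandetanib	BrainC	7
Ado-trastuzumab emtansine	Lung cancer	6
Axitinib	Liver cancer	6
Cabozantinib	KNC	6
Pazopanib	PACA	6
Pazopanib	THC	6
Ramucirumab	CRC	6
Sunitinib	THC	6
Afatinib	GCA	5
Axitinib	CRC	5
Lapatinib	PACA	5
Panitumumab	BRCA	5
Pazopanib	Liver cancer	5
Peginterferon Alfa-2b	Lymphoma	5
Pomalidomide	Lymphoma	5
Ramucirumab	KNC	5
Regorafenib	Sarcoma	5
Toremifene	PCa	5
Vemurafenib	CRC	5
Ziv-aflibercept	Lung cancer	5
Afatinib	CRC	4
Axitinib	THC	4
Gefitinib	PACA	4
Pazopanib	GCA	4
Pazopanib	CRC	4
Pertuzumab	GCA	4
Regorafenib	KNC	4
Regorafenib	PACA	4
Regorafenib	Melanoma	4
Tamoxifen citrate	PCa	4
Tositumomab and Iodine I 131 Tositumomab	Leukemia	4
Vandetanib	KNC	4
Vemurafenib	THC	4
Ziv-aflibercept	KNC	4
Ado-trastuzumab emtansine	GCA	3
Afatinib	PACA	3
Bevacizumab	THC	3
Cabozantinib	PACA	3
Cabozantinib	Sarcoma	3
Dabrafenib	THC	3
Fulvestrant	PCa	3
Pertuzumab	Lung cancer	3
Vandetanib	PACA	3
Ziv-aflibercept	BrainC	3
Axitinib	Sarcoma	2
Axitinib	PACA	2
Axitinib	GCA	2
Cabozantinib	Liver cancer	2
Denileukin diftitox	KNC	2
Estramustine	BRCA	2
Gefitinib	THC	2
Vandetanib	GCA	2
Bexarotene	KS	1
Cabozantinib	CRC	1
Cabozantinib	GCA	1
Cetuximab	THC	1
Crizotinib	THC	1
Dabrafenib	KNC	1
Dabrafenib	Liver cancer	1
Dabrafenib	CRC	1
Degarelix	BRCA	1
Erlotinib	THC	1
Lapatinib	THC	1
Peginterferon Alfa-2b	Sarcoma	1
Ramucirumab	PACA	1
Ramucirumab	Sarcoma	1
Regorafenib	THC	1
Ziv-aflibercept	THC	1
Abarelix	BRCA	0
Afatinib	THC	0
Alitretinoin	Lymphoma	0
Bosutinib	GCA	0
Dabrafenib	GCA	0
Dasatinib	GCA	0
Fluoxymesterone	PCa	0
Flutamide	BRCA	0
Methyltestosterone	PCa	0
Nilotinib	GCA	0
Nilutamide	BRCA	0
Panitumumab	THC	0
Ponatinib	GCA	0
Ramucirumab	THC	0
Vemurafenib	GCA	0
Vemurafenib	KNC	0
Vemurafenib	Liver cancer	0
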