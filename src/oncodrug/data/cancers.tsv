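name	abbreviation
Leukemia	Leukemia
Lymphoma	Lymphoma
Breast cancer	BRCA
Lung cancer	Lung cancer
Prostate cancer	PCa
Ovarian cancer	OV
Melanoma	Melanoma
Colorectal cancer	CRC
Kidney cancer	KNC
Stomach cancer	GCA
Brain cancer	BrainC
Multiple myeloma	MM
Pancreatic cancer	PACA
Testicular cancer	TC
Head and neck cancer	HNC
Sarcoma	Sarcoma
Bladder cancer	BCA
Thyroid cancer	THC
Bone cancer	BoneC
Basal cell carcinoma	BCC
Cervical cancer	CC
Gestational trophoblastic disease	GTD
Adrenal cortical carcinoma	ACR
Choriocarcinoma	CCA
Esophageal cancer	EC
Gastroenteropancreatic neuroendocrine tumor	GEP-NET
Kaposi's sarcoma	KS
Liver cancer	Liver cancer
Mesothelioma	Mesothelioma
Myelofibrosis	MF
Penile cancer	PC
Retinoblastoma	RB
Vulvar cancer	VUC
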