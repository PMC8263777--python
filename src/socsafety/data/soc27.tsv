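soc_code	soc_name	abbreviation
BLOOD	Blood and lymphatic system disorders	Blood
CARD	Cardiac disorders	Card
CONG	Congenital, familial and genetic disorders	Cong
EAR	Ear and labyrinth disorders	Ear
ENDO	Endocrine disorders	Endo
EYE	Eye disorders	Eye
GASTR	Gastrointestinal disorders	Gastr
GENRL	General disorders and administration site conditions	Genrl
HEPAT	Hepatobiliary disorders	Hepat
IMMUN	Immune system disorders	Immun
INFEC	Infections and infestations	Infec
INJP	Injury, poisoning and procedural complications	Inj&P
INV	Investigations	Inv
METAB	Metabolism and nutrition disorders	Metab
MUSC	Musculoskeletal and connective tissue disorders	Musc
NEOPL	Neoplasms benign, malignant and unspecified (incl cysts and polyps)	Neopl
NERV	Nervous system disorders	Nerv
PREG	Pregnancy, puerperium and perinatal conditions	Preg
PROD	Product issues	Prod
PSYCH	Psychiatric disorders	Psych
RENAL	Renal and urinary disorders	Renal
REPRO	Reproductive system and breast disorders	Repro
RESP	Respiratory, thoracic and mediastinal disorders	Resp
SKIN	Skin and subcutaneous tissue disorders	Skin
SOCCI	Social circumstances	SocCi
SURG	Surgical and medical procedures	Surg
VASC	Vascular disorders	Vasc
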