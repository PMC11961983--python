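pt_name,pt_code,soc_name,soc_code
Respiratory tract infection,10062352,Infections and infestations,10021881
Pneumonia,10035664,Infections and infestations,10021881
Sepsis,10040047,Infections and infestations,10021881
Septic shock,10040070,Infections and infestations,10021881
Infection,10021789,Infections and infestations,10021881
Cellulitis,10007882,Infections and infestations,10021881
Pseudomonal skin infection,10074862,Infections and infestations,10021881
Malassezia infection,10026655,Infections and infestations,10021881
Protothecosis,10036933,Infections and infestations,10021881
Gastroenteritis astroviral,10070517,Infections and infestations,10021881
Emphysematous cholecystitis,10014535,Infections and infestations,10021881
Sphingomonas paucimobilis infection,10073422,Infections and infestations,10021881
Disseminated trichosporonosis,10075571,Infections and infestations,10021881
Urinary tract infection,10046571,Infections and infestations,10021881
Febrile neutropenia,10016288,Blood and lymphatic system disorders,10005329
Neutropenia,10029354,Blood and lymphatic system disorders,10005329
Thrombocytopenia,10043554,Blood and lymphatic system disorders,10005329
Anaemia,10002034,Blood and lymphatic system disorders,10005329
Leukopenia,10024384,Blood and lymphatic system disorders,10005329
Pancytopenia,10033661,Blood and lymphatic system disorders,10005329
Cytopenia,10066274,Blood and lymphatic system disorders,10005329
Myelosuppression,10028584,Blood and lymphatic system disorders,10005329
Bone marrow failure,10065553,Blood and lymphatic system disorders,10005329
Acute myeloid leukaemia,10000880,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10029104
Acute myeloid leukaemia recurrent,10000886,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10029104
Acute myeloid leukaemia refractory,10076324,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10029104
Myelodysplastic syndrome,10028533,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10029104
Myelodysplastic syndrome transformation,10054678,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10029104
Transformation to acute myeloid leukaemia,10066245,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10029104
Chronic myelomonocytic leukaemia,10009013,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10029104
Juvenile chronic myelomonocytic leukaemia,10023249,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10029104
Angioimmunoblastic T-cell lymphoma refractory,10077077,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10029104
Blastic plasmacytoid dendritic cell neoplasia,10075460,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10029104
Acute erythroid leukaemia,10073478,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10029104
Leukaemic infiltration pulmonary,10024325,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10029104
Leukaemia cutis,10054498,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10029104
Tumour lysis syndrome,10045170,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10029104
Death,10011906,General disorders and administration site conditions,10018065
Pyrexia,10037660,General disorders and administration site conditions,10018065
Disease progression,10061818,General disorders and administration site conditions,10018065
Therapy non-responder,10043414,General disorders and administration site conditions,10018065
General physical health deterioration,10049438,General disorders and administration site conditions,10018065
Multiple organ dysfunction syndrome,10077361,General disorders and administration site conditions,10018065
Injection site reaction,10022095,General disorders and administration site conditions,10018065
Injection site vasculitis,10022132,General disorders and administration site conditions,10018065
Administration site induration,10075560,General disorders and administration site conditions,10018065
Fatigue,10016256,General disorders and administration site conditions,10018065
Platelet count decreased,10035528,Investigations,10022891
White blood cell count decreased,10047942,Investigations,10022891
Neutrophil count decreased,10029366,Investigations,10022891
Haemoglobin decreased,10018884,Investigations,10022891
Blast cell count increased,10059229,Investigations,10022891
FLT3 gene mutation,10068579,"Congenital, familial and genetic disorders",10010331
Respiratory failure,10038695,"Respiratory, thoracic and mediastinal disorders",10038738
Pneumonitis,10035742,"Respiratory, thoracic and mediastinal disorders",10038738
Pleural effusion,10035598,"Respiratory, thoracic and mediastinal disorders",10038738
Interstitial lung disease,10022611,"Respiratory, thoracic and mediastinal disorders",10038738
Cardiac failure,10007554,Cardiac disorders,10007541
Pericarditis,10034484,Cardiac disorders,10007541
Cerebral haemorrhage,10008111,Nervous system disorders,10029205
Lower motor neurone lesion,10024859,Nervous system disorders,10029205
Neutrophilic panniculitis,10077760,Skin and subcutaneous tissue disorders,10040785
Portal vein cavernous transformation,10077552,Hepatobiliary disorders,10019805
Ulcerative duodenitis,10045275,Gastrointestinal disorders,10017947
Nausea,10028813,Gastrointestinal disorders,10017947
Vomiting,10047700,Gastrointestinal disorders,10017947
Diarrhoea,10012735,Gastrointestinal disorders,10017947
Venous aneurysm,10047186,Vascular disorders,10047065
Blood product transfusion dependent,10072959,Social circumstances,10041244
Allogenic stem cell transplantation,10075483,Surgical and medical procedures,10042613
Hypokalaemia,10021015,Metabolism and nutrition disorders,10027433
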