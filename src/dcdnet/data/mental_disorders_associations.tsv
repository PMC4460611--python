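drug	drug_name	disease	weight
DB00904	Ondansetron	Mental disorders	0.89
DB00669	Sumatriptan	Mental disorders	0.85
DB00734	Risperidone	Mental disorders	0.73
DB00490	Buspirone	Mental disorders	0.77
DB01149	Nefazodone	Mental disorders	0.93
DB01142	Doxepin	Mental disorders	0.83
DB01392	Yohimbine	Mental disorders	0.87
DB00540	Nortriptyline	Mental disorders	0.89
DB01224	Quetiapine	Mental disorders	0.82
DB00363	Clozapine	Mental disorders	0.82
DB00477	Chlorpromazine	Mental disorders	0.78
DB00571	Propranolol	Mental disorders	0.75
DB00321	Amitriptyline	Mental disorders	0.69
DB00726	Trimipramine	Mental disorders	0.90
DB00247	Methysergide	Mental disorders	0.87
DB00656	Trazodone	Mental disorders	0.86
DB00315	Zolmitriptan	Mental disorders	0.85
DB00952	Naratriptan	Mental disorders	0.85
DB08810	Cinitapride	Mental disorders	0.84
DB00589	Lisuride	Mental disorders	0.84
DB00268	Ropinirole	Mental disorders	0.84
DB00413	Pramipexole	Mental disorders	0.84
DB00714	Apomorphine	Mental disorders	0.83
DB00248	Cabergoline	Mental disorders	0.83
DB01238	Aripiprazole	Mental disorders	0.82
DB00246	Ziprasidone	Mental disorders	0.82
DB00334	Olanzapine	Mental disorders	0.82
DB01186	Pergolide	Mental disorders	0.82
DB01618	Molindone	Mental disorders	0.82
DB06684	Vilazodone	Mental disorders	0.82
DB01621	Pipotiazine	Mental disorders	0.82
DB01616	Alverine	Mental disorders	0.82
DB01200	Bromocriptine	Mental disorders	0.82
DB00216	Eletriptan	Mental disorders	0.81
DB01622	Thioproperazine	Mental disorders	0.79
DB01614	Acepromazine	Mental disorders	0.79
DB00960	Pindolol	Mental disorders	0.77
DB04946	Iloperidone	Mental disorders	0.76
DB08807	Bopindolol	Mental disorders	0.75
DB08815	Lurasidone	Mental disorders	0.75
DB06216	Asenapine	Mental disorders	0.74
DB01049	Ergoloid mesylate	Mental disorders	0.74
DB05271	Rotigotine	Mental disorders	0.72
DB01267	Paliperidone	Mental disorders	0.72
DB01359	Penbutolol	Mental disorders	0.60
DB00866	Alprenolol	Mental disorders	0.60
DB00696	Ergotamine	Mental disorders	0.56
DB00998	Frovatriptan	Mental disorders	0.55
DB00918	Almotriptan	Mental disorders	0.55
DB00953	Rizatriptan	Mental disorders	0.53
DB00320	Dihydroergotamine	Mental disorders	0.50
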