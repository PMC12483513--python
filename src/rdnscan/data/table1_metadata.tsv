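taxon_label	phylum	isolation_source	rdnE_id	rdnI_id	focal
Acinetobacter baumannii BJAB0715	Proteobacteria	Fresh water	2562302616	2562302617	false
Acinetobacter baumannii XH858	Proteobacteria	Human sputum	2686809281	2686809282	false
Burkholderia sp. TSV86	Proteobacteria	Water	2766166119	2766166118	false
Cellulophaga baltica 18	Bacteroidota	Water	2815949879	2815949878	false
Chryseobacterium indologenes NBRC 14944	Bacteroidota	Human trachea	2565567985	2565567984	false
Chryseobacterium populi CF314	Bacteroidota	Soil rhizosphere	2511231970	2511231971	false
Chryseobacterium sp. IHB B 17019	Bacteroidota	Soil undefined subtype	2686963654	2686963655	false
Cronobacter turicensis 564	Proteobacteria	Human undefined subtype	2532469359	2532469360	false
Cronobacter turicensis z3032	Proteobacteria	Human blood culture	646327905	646327906	false
Endozoicomonas numazuensis DSM 25634	Proteobacteria	Marine sponge	2574519540	2574519541	false
Paenibacillus elgii M63	Firmicutes	Hot spring	2744846532	2744846531	false
Paenibacillus sp. Aloe-11	Firmicutes	Soil rhizosphere	2549870597	2549870598	false
Prevotella jejuni CD3:33	Bacteroidota	Human intestine biopsy	2804797915	2804797916	true
Prevotella sp. C561	Bacteroidota	Human respiratory tract	2514485316	2514485315	false
Prevotella sp. F0108	Bacteroidota	Human oral cavity	647936965	647936966	false
Proteus mirabilis BB2000	Proteobacteria	Human intestine biopsy	2546214711	2546214712	true
Pseudomonas ogarae F113	Proteobacteria	Soil rhizosphere	2511826458	2511826457	true
Pseudomonas syringae pv. Coriandricola ICMP 12471	Proteobacteria	Undefined	2714543877	2714543878	false
Rothia dentocariosa C6B	Actinobacteriota	Human oral cavity	2611822673	2611822674	true
Tannerella forsythia ATCC 43037	Bacteroidota	Human oral cavity	2512371376	2512371377	false
Taylorella asinigenitalis MCE3	Proteobacteria	Mammal reproductive system	2511725471	2511725470	false
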