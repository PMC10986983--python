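# Regional bee taxonomy fixture: taxid, name, rank, parent_taxid.
# Real NCBI taxids are used where available in the bundled records;
# nodes without a recorded NCBI id carry synthetic fixture ids >= 900000.
1	root	no_rank	1
6656	Arthropoda	phylum	1
50557	Insecta	class	6656
7399	Hymenoptera	order	50557
7458	Apidae	family	7399
77572	Halictidae	family	7399
900011	Megachilidae	family	7399
900012	Andrenidae	family	7399
900001	Bombus	genus	7458
7459	Apis	genus	7458
900003	Svastra	genus	7458
81082	Melissodes	genus	7458
900009	Triepeolus	genus	7458
900004	Halictus	genus	77572
900006	Lasioglossum	genus	77572
900007	Agapostemon	genus	77572
900010	Augochloropsis	genus	77572
900005	Megachile	genus	900011
900008	Andrena	genus	900012
207634	Bombus griseocollis	species	900001
28643	Bombus pensylvanicus	species	900001
309941	Bombus affinis	species	900001
132113	Bombus impatiens	species	900001
239130	Bombus citrinus	species	900001
900013	Bombus auricomus	species	900001
900014	Bombus vagans	species	900001
900015	Bombus bimaculatus	species	900001
7460	Apis mellifera	species	7459
156364	Svastra obliqua	species	900003
900016	Melissodes bimaculatus	species	81082
900017	Melissodes trinodis	species	81082
599269	Melissodes communis	species	81082
77576	Halictus ligatus	species	900004
88517	Lasioglossum pectorale	species	900006
88495	Lasioglossum pilosum	species	900006
1038993	Lasioglossum albipenne	species	900006
1040006	Lasioglossum paradmirandum	species	900006
1479665	Agapostemon splendens	species	900007
900019	Augochloropsis metallica	species	900010
900020	Augochloropsis metallica fulgida	subspecies	900019
1452476	Megachile brevis	species	900005
586910	Megachile latimanus	species	900005
205204	Andrena wilkella	species	900008
900018	Andrena rudbeckiae	species	900008
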