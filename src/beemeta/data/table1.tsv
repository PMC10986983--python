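bee_id	sanger_taxid	sanger_taxon	morph_taxid	morph_taxon	metabarcode_detected
A-391-1	ND	ND	207634	Bombus griseocollis	Y
A-391-2	207634	Bombus griseocollis	207634	Bombus griseocollis	Y
A-391-3	ND	ND	207634	Bombus griseocollis	Y
A-391-4	28643	Bombus pensylvanicus	28643	Bombus pensylvanicus	Y
A-391-5	ND	ND	900013	Bombus auricomus	Y
A-391-6	ND	ND	207634	Bombus griseocollis	Y
A-391-7	207634	Bombus griseocollis	207634	Bombus griseocollis	Y
A-391-8	207634	Bombus griseocollis	207634	Bombus griseocollis	Y
A-391-9	28643	Bombus pensylvanicus	28643	Bombus pensylvanicus	Y
A-391-10	309941	Bombus affinis	309941	Bombus affinis	Y
A-391-11	132113	Bombus impatiens	132113	Bombus impatiens	Y
A-391-12	7460	Apis mellifera	7460	Apis mellifera	Y
A-391-13	156364	Svastra obliqua	156364	Svastra obliqua	Y
A-391-14	156364	Svastra obliqua	156364	Svastra obliqua	Y
A-391-15	81082	Melissodes	81082	Melissodes	N
A-391-16	77576	Halictus ligatus	77576	Halictus ligatus	Y
A-391-17	77576	Halictus ligatus	77576	Halictus ligatus	Y
A-391-18	1452476	Megachile brevis	900005	Megachile	Y
A-391-19	1452476	Megachile brevis	900005	Megachile	Y
A-391-20	77576	Halictus ligatus	77576	Halictus ligatus	Y
A-466-1	7460	Apis mellifera	7460	Apis mellifera	Y
A-466-2	ND	ND	900014	Bombus vagans	Y
A-466-3	132113	Bombus impatiens	132113	Bombus impatiens	Y
A-466-4	7458	Apidae	900016	Melissodes bimaculatus	Y
A-466-5	81082	Melissodes	81082	Melissodes	Y
A-466-6	ND	ND	900017	Melissodes trinodis	Y
A-466-7	77576	Halictus ligatus	77576	Halictus ligatus	Y
A-466-8	ND	ND	900006	Lasioglossum	N
A-825-1	28643	Bombus pensylvanicus	28643	Bombus pensylvanicus	Y
A-825-2	28643	Bombus pensylvanicus	28643	Bombus pensylvanicus	Y
A-825-3	207634	Bombus griseocollis	207634	Bombus griseocollis	Y
A-825-4	586910	Megachile latimanus	586910	Megachile latimanus	Y
A-825-5	156364	Svastra obliqua	81082	Melissodes	Y
A-825-6	7458	Apidae	900016	Melissodes bimaculatus	Y
A-825-7	7458	Apidae	900016	Melissodes bimaculatus	Y
A-825-8	ND	ND	900009	Triepeolus	N
A-825-9	ND	ND	900009	Triepeolus	N
A-825-10	ND	ND	900009	Triepeolus	N
A-825-11	77572	Halictidae	900020	Augochloropsis metallica fulgida	N
A-825-12	1479665	Agapostemon splendens	900007	Agapostemon	Y
J-825-1	239130	Bombus citrinus	239130	Bombus citrinus	Y
J-825-2	ND	ND	900015	Bombus bimaculatus	Y
J-825-3	7460	Apis mellifera	7460	Apis mellifera	Y
J-825-4	7460	Apis mellifera	7460	Apis mellifera	Y
J-825-5	ND	ND	900018	Andrena rudbeckiae	N
J-825-6	599269	Melissodes communis	81082	Melissodes	Y
J-825-7	ND	ND	900018	Andrena rudbeckiae	N
J-825-8	81082	Melissodes	900017	Melissodes trinodis	Y
J-825-9	81082	Melissodes	900017	Melissodes trinodis	Y
J-825-11	77576	Halictus ligatus	77576	Halictus ligatus	Y
J-825-12	77576	Halictus ligatus	77576	Halictus ligatus	Y
J-825-14	88517	Lasioglossum pectorale	900006	Lasioglossum	Y
J-825-15	88495	Lasioglossum pilosum	900006	Lasioglossum	Y
J-825-16	88517	Lasioglossum pectorale	900006	Lasioglossum	Y
J-880-1	ND	ND	900018	Andrena rudbeckiae	Y
J-880-2	ND	ND	900018	Andrena rudbeckiae	Y
J-880-3	205204	Andrena wilkella	900008	Andrena	Y
J-880-5	205204	Andrena wilkella	900018	Andrena rudbeckiae	Y
J-880-6	77576	Halictus ligatus	77576	Halictus ligatus	Y
J-880-7	77576	Halictus ligatus	77576	Halictus ligatus	Y
J-880-8	77576	Halictus ligatus	77576	Halictus ligatus	Y
J-880-9	77576	Halictus ligatus	77576	Halictus ligatus	Y
J-880-10	88495	Lasioglossum pilosum	900006	Lasioglossum	Y
J-880-11	1038993	Lasioglossum albipenne	900006	Lasioglossum	Y
J-880-12	ND	ND	900006	Lasioglossum	Y
J-880-13	1040006	Lasioglossum paradmirandum	900006	Lasioglossum	Y
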