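# Reference hit list of lung-function-associated mouse miRNAs
# (28 entries: 16 upregulated, 12 downregulated; transcribed mature sequences)
mirna	direction	mature_seq
mmu-miR-501-3p	UP	AAUGCACCCGGGCAAGGAUUUG
mmu-miR-340-3p	UP	UCCGUCUCAGUUACUUUAUAGC
mmu-miR-378a-3p	UP	ACUGGACUUGGAGUCAGAAGG
mmu-miR-1247-5p	UP	ACCCGUCCCGUUCGUCCCCGGA
mmu-miR-342-3p	UP	UCUCACACAGAAAUCGCACCCGU
mmu-miR-148a-3p	UP	UCAGUGCACUACAGAACUUUGU
mmu-miR-369-5p	UP	AGAUCGACCGUGUUAUAUUCGC
mmu-miR-410-3p	UP	AAUAUAACACAGAUGGCCUGU
mmu-miR-431-5p	UP	UGUCUUGCAGGCCGUCAUGCA
mmu-miR-148b-3p	UP	UCAGUGCAUCACAGAACUUUGU
mmu-miR-212-3p	UP	UAACAGUCUCCAGUCACGGCCA
mmu-miR-183-5p	UP	UAUGGCACUGGUAGAAUUCACU
mmu-miR-411-5p	UP	UAGUAGACCGUAUAGCGUACG
mmu-miR-212-5p	UP	ACCUUGGCUCUAGACUGCUUACU
mmu-miR-127-3p	UP	UCGGAUCCGUCUGAGCUUGGCU
mmu-miR-146b-5p	UP	UGAGAACUGAAUUCCAUAGGCU
mmu-miR-181a-5p	DOWN	AACAUUCAACGCUGUCGGUGAGU
mmu-miR-10a-5p	DOWN	UACCCUGUAGAUCCGAAUUUGUG
mmu-miR-181b-5p	DOWN	AACAUUCAUUGCUGUCGGUGGGU
mmu-miR-652-3p	DOWN	AAUGGCGCCACUAGGGUUGUG
mmu-miR-146a-5p	DOWN	UGAGAACUGAAUUCCAUGGGUU
mmu-miR-151-3p	DOWN	CUAGACUGAGGCUCCUUGAGG
mmu-miR-195a-5p	DOWN	UAGCAGCACAGAAAUAUUGGC
mmu-miR-503-3p	DOWN	GAGUAUUGUUUCCACUGCCUGG
mmu-miR-203-3p	DOWN	GUGAAAUGUUUAGGACCACUAG
mmu-miR-676-3p	DOWN	CCGUCCUGAGGUUGUUGAGCU
mmu-miR-7656-3p	DOWN	ACAGGCUGUCUGAUCCCACGGU
mmu-miR-30f	DOWN	GUAAACAUCCGACUGAAAGCUC
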