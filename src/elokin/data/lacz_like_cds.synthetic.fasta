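>lacZ_like_synthetic 1023-codon CDS; SYNTHETIC stand-in for the lacZ gene:
AUGGAAUGGAGCAGCACAUUGGAAAUUAUGGCCCACAUCGAAGAAGCCCUCACUGGCACU
GCGGGUUGGUAUCUGCCGAUCGAUGCAGCUGCGGUCCCCGUCAUUGUCUACCCGGAAGGU
GGGCAAAAGCGCGGUUGGCUGGCCGCCCUGUGGCAUGACUUUGUGUUCGCCCAAAUUACU
UCUGUAGAGGGCAACGUUGAUGCCGGGCAGCGGGCCGAACAUCGCGGAACCUUUAAAAUU
AAAAAAGGCGGGACCCGUGUGGAUAGCGUCAGCUUGGGGAAACCGCUGUUUGGGGUUUGC
AUCGAGAUGGAAAGUGCUUGUCGCGCCAGCGAUCAGUCGUUUCUGAGGCUCGUUAGUAGC
GAGGCAGCGUAUGAAAUAACCCCUGCCCAACUGCACGUUUAUCCCAUGCUUUACCGUUAU
UGGGGUUCGUCCCUGUGGAUUUAUCAUCUUCUAUUGCUGAGCAUUCUGACCGGCCCUUCU
CGCCGUAAAGAUAAUCUGCUUACCGAAGCAGAUAAAUUUGGUGUCGUGAUCCCGUGGGCU
UGGAAGGCUCACAUUCCAUUGGCGGCUAACUACAGUCUGCACCAGGGUAAACUGGAGUAU
CUGUCUUCCAUGCACAAUGGCUUUAUCCCGCAGGAGUUCACCAACGAGGGCGCGUCACAU
CGGUGGGGGAGCUUUGUGGAUGAUGCGGGAUUACACACAUCCCGCUCGGGUGUGUUCGGC
GAAUUUGCAAUGGUGGCGCUGAACAAACGUGGGCUUGGCCUGCUGUUGACUCAGCCGGAC
UGGAGUCAUAUCUUCAUGUUCGCCGGACAGCGUGACGUUAUGGUUGGCCAGGUGCCGACC
UACAUUAUUUACGACAUCAAUCCUGAUUAUGAGGCGACGCGUGGUUGGUGUAUUGAUGAU
GCUCAUUGGUCGCUGCAGAUGAACGUUCUGAUCCAGGCGGGCGUGAGUCCGGUUGGCACG
UCGUUACUGAAUUUAGUGGUCUGCGCCGCGGCGAUCCUGCAUAUCCGCGCAGAUGUGGGG
AUCCUGGCGCGCUGGAAGAAGGAAAUGCUUCGUGCUCCACGCCACCAGGCGGCGAAGAAC
CACGGCGAGUAUGUACCGCCGUGGCUGUUUCCGCUGGCCUUUGUGAUGCCUGUAAACACU
CGUCCAAUGCCAGCUCAAGAAAGACAAGACGGUUUGCUGGAACGUUACGCCUUCGGACUG
GAGAAUAAUGACCGUAACUGGGGAGAACAAGAAAUGAUUUUGGACGGUACGCGCACUUCA
GCAACACCUUGGAGCCCCACCGAUAUUUUGGUACGUACCGAUCUGCUGGCGCACACAGAA
UACGAAUGGGAUGGUGUUCGUCAGGCUGUUGCGCGCUUUGAAGGCAAGGGUUUGUACGUG
UGGGUAGAUGCGAUUAUUGGUUUGUACCGCGUUGGCGAGCUCUAUUCCGUUGGCCCCCUG
GAGUCUAUUCAGGUGGCAGCGGGUGAACUACUGAUCUGCCGUGCGGGCCCGGGCCUGGAU
GUGAUUCUCAACUGGAACUACCUUAGUCAUACGCUUUGGUUCCAGAACGAUUCUGCCGUG
UGGCAUGAUGCGAAGGGCGUGCUUCUUGUGGGCCUCGAGUUCGGCGUUGGUAAGGUUCCG
CAAUUUGCGGCAACGUGUCGAGGCGUUCUGGACACCGAACUUGCCGACCCAAUGUUAAGC
AACAUUGGUCGAACUGGUCUGAAUGCGCCCUUUACCGCGGUAAUGGAUCAGGGUGUAAUA
GACGUUUUCAUGCGUACUACCCAUUCCUCACAGGUCUUUGGCAAGGUGUUCCUGUUCGCG
UUAGAUAUUUUUAUCCUGUUCCACACGCUCUGUCGGCUCUUCGAACGACAAGACGCGGUC
CGCGACCUGACGGAUUCGAGCUUGUUAGGACGCCGUCUGACGAAGCCGCCGGACGUAAAU
CCGCAAGUGCAGCUGAAUGGCGAACUGCAGAUGAUCCCGUUUUCUGGUAAGUGGGCGGCA
CUCCUUACAACGCCAGAUUCAAAUCUAACGCUGGAAAUGACGUAUCGUAACCGCCCAAAU
GAACCUAAGAUCGAUGAAGAAGGUCAAUUAAACUCGAUGAACCAAAUCUCAAUCUGGCUG
AUAUGGUAUGAAUGGUUCAUGCAGCCCCAGGUCUAUGUCCUGUGGCAUGGAGUAAAUGAG
GCAGCUCCGGGCGGGAAAAACUGGUGCGCAAUGAUGGAGGUCAGUAGUGUUAUGUCGCGG
CAGAAGCUCAUUAUGGCCGAAUAUUCCCAGGCGGCAUGGAAACAGGUACCGGCAAAUACC
CGCAUUGCCGGCGAAACCAAUACCCGCUUACGCCUGCGUACCUUUAAAAGCGCCGGACUG
GCCAUUACCGUGAUUGUCGCUGGCGAUUCAGAAGAUCGUGCGAUUCUGACCGAGGACAAU
AUAUUUGAUUACACGGCUAACGCAAUCGCAACCGGUUGGGGUGUCUGGAAAGGGGAACAU
AGCGAAAUGGAUAAAUUUUGGUCCCUCGAAGCAGCAGAAAUGCUAGGCGACUUAAUUUGC
CUGACCUGGAAGGAUUGGGCCUGGAUCUUUAUCGCUACAGCAUCGGCCGUGGCGGUGGGU
GAUCAGUUAGAAUGCCAAGUCGACUUAACCCGCCGCGAAACGGCAUGGGGUUCUGUUACG
AACGACCAUCGCGAAACGAUCAACUCACUGGUCCCUAUUCCGAUGAGCUCUGGCAUUACC
GAGGCACUGUGGGGGCCGAUCAUUCAGCGUAUUAGCGGCCAAGGCAACGUCCUGAUGAAG
GUGUUCAUUUACCCGUCCGAUUUAGUUUUCGCCUUUCAGACUUAUCGGCGUGAAUGGUAU
CCGCGCCGCGACUUGCAGGCUCUCCAAGAAUGGGAACCAGAGUGUCCAGCCCGUUUUAAU
AGAAUCUUACUGGACGUAGCGAAUAUCGCUAUUGCUAAUGUGGAUGCGACCGAUGCCAAG
UCUUGGCUGGCGAGCGGUAUUCUGAAAACAAACUUGCGAUUCCUGGCCUUACAGGCGAGU
GUGUGGAAAUAUAUCCAACAAGUGCAGUCCCCGGCGCAGAAGUUGAACGAGAUGCUGGCC
UUUGUGACCUAA
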