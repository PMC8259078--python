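>YER148W gene=SPT15 upstream_flank=40 downstream_flank=40 assembly=R64 source=SGD
TCCAACATAAACAGGTGTATCAAGAGAAACTTTTTTAATTATGGCCGATGAGGAACGTTTAAAGGAGTTT
AAAGAGGCAAACAAGATAGTGTTTGATCCAAATACCAGACAAGTATGGGAAAACCAGAATCGAGATGGTA
CAAAACCAGCAACTACTTTCCAGAGTGAAGAGGACATAAAAAGAGCTGCCCCAGAATCTGAAAAAGACAC
CTCCGCCACATCAGGTATTGTTCCAACACTACAAAACATTGTGGCAACTGTGACTTTGGGGTGCAGGTTA
GATCTGAAAACAGTTGCGCTACATGCCCGTAATGCAGAATATAACCCCAAGCGTTTTGCTGCTGTCATCA
TGCGTATTAGAGAGCCAAAAACTACAGCTTTAATTTTTGCCTCAGGGAAAATGGTTGTTACCGGTGCAAA
AAGTGAGGATGACTCAAAGCTGGCCAGTAGAAAATATGCAAGAATTATCCAAAAAATCGGGTTTGCTGCT
AAATTCACAGACTTCAAAATACAAAATATTGTCGGTTCGTGTGACGTTAAATTCCCTATACGTCTAGAAG
GGTTAGCATTCAGTCATGGTACTTTCTCCTCCTATGAGCCAGAATTGTTTCCTGGTTTGATCTATAGAAT
GGTGAAGCCGAAAATTGTGTTGTTAATTTTTGTTTCAGGAAAGATTGTTCTTACTGGTGCAAAGCAAAGG
GAAGAAATTTACCAAGCTTTTGAAGCTATATACCCTGTGCTAAGTGAATTTAGAAAAATGTGATGGGGAA
GGAGTAGACGAAAAGAAAAAAAGGTTTTCTATT
>YEL021W gene=URA3 upstream_flank=40 downstream_flank=40 assembly=R64 source=SGD
ACTGCACAGAACAAAAACCTGCAGGAAACGAAGATAAATCATGTCGAAAGCTACATATAAGGAACGTGCT
GCTACTCATCCTAGTCCTGTTGCTGCCAAGCTATTTAATATCATGCACGAAAAGCAAACAAACTTGTGTG
CTTCATTGGATGTTCGTACCACCAAGGAATTACTGGAGTTAGTTGAAGCATTAGGTCCCAAAATTTGTTT
ACTAAAAACACATGTGGATATCTTGACTGATTTTTCCATGGAGGGCACAGTTAAGCCGCTAAAGGCATTA
TCCGCCAAGTACAATTTTTTACTCTTCGAAGACAGAAAATTTGCTGACATTGGTAATACAGTCAAATTGC
AGTACTCTGCGGGTGTATACAGAATAGCAGAATGGGCAGACATTACGAATGCACACGGTGTGGTGGGCCC
AGGTATTGTTAGCGGTTTGAAGCAGGCGGCGGAAGAAGTAACAAAGGAACCTAGAGGCCTTTTGATGTTA
GCAGAATTGTCATGCAAGGGCTCCCTAGCTACTGGAGAATATACTAAGGGTACTGTTGACATTGCGAAGA
GCGACAAAGATTTTGTTATCGGCTTTATTGCTCAAAGAGACATGGGTGGAAGAGATGAAGGTTACGATTG
GTTGATTATGACACCCGGTGTGGGTTTAGATGACAAGGGAGACGCATTGGGTCAACAGTATAGAACCGTG
GATGATGTGGTCTCTACAGGATCTGACATTATTATTGTTGGAAGAGGACTATTTGCAAAGGGAAGGGATG
CTAAGGTAGAGGGTGAACGTTACAGAAAAGCAGGCTGGGAAGCATATTTGAGAAGATGCGGCCAGCAAAA
CTAAAAAACTGTATTATAAGTAAATGCATGTATACTAAACTCAC
>YAR015W gene=ADE1 upstream_flank=40 downstream_flank=40 assembly=R64 source=SGD
CATTGCTTACAAAGAATACACATACGAAATATTAACGATAATGTCAATTACGAAGACTGAACTGGACGGT
ATATTGCCATTGGTGGCCAGAGGTAAAGTTAGAGACATATATGAGGTAGACGCTGGTACGTTGCTGTTTG
TTGCTACGGATCGTATCTCTGCATATGACGTTATTATGGAAAACAGCATTCCTGAAAAGGGGATCCTATT
GACCAAACTGTCAGAGTTCTGGTTCAAGTTCCTGTCCAACGATGTTCGTAATCATTTGGTCGACATCGCC
CCAGGTAAGACTATTTTCGATTATCTACCTGCAAAATTGAGCGAACCAAAGTACAAAACGCAACTAGAAG
ACCGCTCTCTATTGGTTCACAAACATAAACTAATTCCATTGGAAGTAATTGTCAGAGGCTACATCACCGG
ATCTGCTTGGAAAGAGTACGTAAAAACAGGTACTGTGCATGGTTTGAAACAACCTCAAGGACTTAAAGAA
TCTCAAGAGTTCCCAGAACCAATCTTCACCCCATCGACCAAGGCTGAACAAGGTGAACATGACGAAAACA
TCTCTCCTGCCCAGGCCGCTGAGCTGGTGGGTGAAGATTTGTCACGTAGAGTGGCAGAACTGGCTGTAAA
ACTGTACTCCAAGTGCAAAGATTATGCTAAGGAGAAGGGCATCATCATCGCAGACACTAAATTCGAATTC
GGTATTGACGAAAAGACCAATGAAATTATTCTAGTGGACGAGGTGCTAACGCCAGACTCCTCTAGATTCT
GGAACGGTGCCTCTTATAAGGTAGGAGAATCCCAAGATTCTTACGATAAGCAATTTTTAAGAGACTGGCT
TACTGCTAATAAGTTGAACGGTGTTAACGGCGTCAAAATGCCCCAAGACATTGTCGACAGGACAAGGGCC
AAATATATAGAGGCTTATGAAACATTGACAGGGTCTAAATGGTCTCACTAACGTGATTTACATATACTAC
AAGTCGCCAGTGTAACTCCTC
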