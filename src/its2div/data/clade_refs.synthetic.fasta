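; synthetic clade anchor sequences, one per clade A-I
>A synthetic_anchor_clade_A
CCTACTGTTGCCTGTAGAGGAGGAGACAACGGTAGTTCGATTCATAAAGCACACGTGTCTAAACTGGTAA
CTCTGTGTTCTGCAGCCCAGTTTGACTTACTGACAGTGTGAGCGCCTGCTAAGGTTCCCCGAATTTGGCG
GCCAGTCTTGCAAGAGGTGATTATCTCCCTTAAATAAGACTCGGGTCTCTCGTTTATTTCTAGTATATCA
CAGGGAAGCGCCATAGGTCGGCGCAAGTCCGTCATTGCCCCTGGCCCGCC
>B synthetic_anchor_clade_B
ACTCCGTTACCGCAACTAGACGGGTCCGTACTGTTAGGCAGTCATGAGCCAATCCAGCTCGTGCTTGCAG
TGTAAGTTGCCCCTTCAAAACCTAGTGGGAGTAATGCCTTCATGTGAGGTTAGCTAGTGCATTCGCGTCG
AGTATTGGAGGTCAACCCCGAAATTAATTCGCGTCAAAGTTCTACATCCCCGAGTAGTGACTGTAGTGCA
AGTTGTTGCGACAAGTTGTCATAGCAGCAGGGGACTGATTATACAGTTTT
>C synthetic_anchor_clade_C
CCTCCGCTGAAAGGATTTCTCTCTAATTTATAAGCGCAGTTGATTTCTATTAGCTTCTCGTGCTCACTTG
CCCCATTGACCAGGTAAGCAACCTGCAAGTGAGTGCGACCAAACCAGCGAGGGGACCGTATCAACGGGTT
ACATGTTAGGACACACAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTCCCGCGCACACATGT
CAAGCGCCGAAGACGGGAAAACCGGAGTGGTGACAAGCTAAACCTGCGGT
>D synthetic_anchor_clade_D
TTAGTTTGACAGCCACTTGTATGCGGCGGGATGTGATGAACACGAGGCTGATGTCGAAAGATATTTCTTA
TGAAGTGGACCGTAGTCAAAGGTCTAAGGAATTGTCGAGTGCGTACTTATAAGCCCGGATATGCACCTCG
CAGAGCTTTCACAATTCACCCTGTCCGCGGTCAACGTAAGATCAAGCGATATAGTCACCTGGTTGTTTCA
TGTCCTAAAGATAGTCTCGATCAGGATAGCCATGAACTCTGAAGAAGCGA
>E synthetic_anchor_clade_E
ACGCCGGGTTCACGCTCGTAGTTACTGCAAAGCCAGTGTCTCTCAAATTGTATCATGGCGGTCGGTATGT
CCGAGACACGTCTAAATCATGGTCTCATGTACGAATGCCGGGACGCACGGCAGTCTGCAGAGAGGTATTG
AGCGAGTGTCACGCAAGTCTAGGCCCATGTGCCGCTGAGAGAGCGCTGCCAAGTTGGCCACGGGGACTCT
TATGGCTCCGTAAAAGTTCTTCTTCTTGAGGGATACCTTAGGCGGTTCCC
>F synthetic_anchor_clade_F
GCCACATCCCATCGGAGACATCCTGGGGAGCGTTCAGTGGGGCCATCAAGTACGACCGCGACCAGAACCT
TGTTTGGTGTTGACGCATGGAGCCGCCAGGTCTACTACATCCCATTTCCATACATGCCCTTTCGCGTAAG
TACCGCGTTCATAACCGCATCCCCTTAAGTCGTTAGCGAACCTTTTCGACTACAGTGACGGTGCGTGCTA
AACATTCCTCTTGCTCCACACAACGCGGCTAATCCTAAGCATTCCCTTCG
>G synthetic_anchor_clade_G
CCCAGTCTAGACTACTGTTTCGAAACCCCGATTTGAGATTTCCAGTCGGCACCATCGAGGCATTAGTTTC
TGGTTGTGTTCAGATTCAGGCACGTTCCCCTCATAACCGTCGGAGGCCCAGTAGGAGCAAAGAGTACATT
CTCAGGCTGTCTTCTCTAAACGCACCTGGGTCAGAATGCCCTGTTGACGTGTCTAAATCATAGCCTTAGC
CACTACGTAGCAGGATATAGGAGGGTAGGTAGTATAGAGATGGGTGGCCC
>H synthetic_anchor_clade_H
CGGCGATAATCTAAGGCTGAACAACGAACCGAATTAGGGAGGCAGCACGATGGCCTTCTCCTACAAACGA
TTATTCTGATCTCTTGGTCTTGAGCAACCTAGCCCAAGTCGTATCCCTCCTGGTCCGGCTTGCCGAGCCA
GAATTAGTTCTCCTATCCTCTCCTCGTGAACAGCGATGAGCAGGCATGATACGCTCATCATGTTAATCGG
GGCCTCTGGCCGGGAGCCGTAGCGGCACCAATCGTGATCTGGTACCCAGC
>I synthetic_anchor_clade_I
TTCAGCCTCATTCACCTTCTGGGTACCCATAGGCTCAATCTGACCCTTTGCATCGACAGGGCTGTTTGAC
ACACTTCTTGTAAAGTTTGAGGTCACTATAAGCATCCAGCGCCCAAAGCAGGTCGGTTCCGCGAGTTGAG
AGAATGCGATAGTAGACAGGCACTGGCACGTATTGAGATACCAATCTGTATGTTGAATCAGTGAGCTGGA
CGATGGTTGGTGTTCGATCCTCCAGGCCAGTATCGCCTAGCTGGTGCTCG
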