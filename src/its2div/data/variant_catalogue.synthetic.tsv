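# synthetic named-variant catalogue: exact-match lookup
name	clade	sequence
C3	C	CCTCCGCTGAAAGGATTTCTCTCTAATTTATAAGCGCAGTTGATTTCTATTAGCTTCTCGTGCTCACTTGCCCCATTGACCAGGTAAGCAACCTGCAAGTGAGTGCGACCAAACCAGCGAGGGGACCGTATCAACGGGTTACATGTTAGGACACACAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTCCCGCGCACACATGTCAAGCGCCGAAGACGGGAAAACCGGAGTGGTGACAAGCTAAACCTGCGGT
C3gulf	C	CCTCCGCTGAAAGGATTTCTCTCGAATTTATAAGCGCAGTTGATTTCTATTAGCTTCTCGTGCTCACTTGCCCCATTGACCAGGTAAGCAACCTGCAAGTGAGTGCGACCAAACCAGCGAGGGGACCGTATCAACGGGTTACATGTTAGGACACACAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTCCCGCGCACACATGTCAAGCGCCGAAGACGGGAAAACCGGAGTGGTGACAAGCTAAACCTGCGGT
C3c	C	CCTCCGATGAAAGGATTTCTCTCTAATTTATAAGCGCAGTTGATTTCTATTAGCTTCTCGTGCTCACTTGCCCCATTGACCAGGTAAGCAACCTGCAAGTGAGTGCGACCAAACCAGCGAGGGGACCGTATCAACGGGTTACATGTTAGGACACACAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTCCCGCGCACACATGTCAAGCGCCGAAGACGGGAAAACCGGAGTGGTGACAAGCTAAACCTGCGGT
C3aq	C	CCTCCGCTGAAAGGATTTCTCTCTAATTTATAAGCGCAGTTGATTTCTATTAGCTTCTCGTGCTCACTTGGCCCATTGACCAGGTAAGCAACCTGCAAGTGAGTGCGACCAAACCAGCGAGGGGACCGTATCAACGGGTTACATGTTAGGACACACAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTCCCGCGCACACATGTCTAGCGCCGAAGACGGGAAAACCGGAGTGGTGACAAGCTAAACCTGCGGT
C3am	C	CCTCCGCTGAAAGGATTTCTCTCTAATTTATAAGCGCAGTTGATTTCTATTAGCTTCTCGTGCTCACTTGCCCCATTGATCAGGTAAGCAACCTGCAAGTGAGTGCGACCAAACCAGCGAGGGGACCGTGTCAACGGGTTACATGTTAGGACACACAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTCCCGCGCACACATGTCAAGCGCCGAAGACGGGAAAACCGGAGTGGTGACAAGCTAAACCTGCGGT
C3d	C	CCTCCGCTGAAAGGATTTCTCTCTAATTTATAAGCGCAGTTGATTTCTATTAGCTTCTCGTGCTCACTTGCCCCATTGACCAGGTAAGCAACCTGCAAGTGAGTGCGACCAAAACAGCGAGGGGACCGTATCAACGGGTTACATGTTAGGACACACAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTCCCGCGCACACATGTCAAGCGCCGAAGACGGGAAAACCGGAGTGGTGACAAGCTAAACCTGCGGT
C3i	C	CCTCCGCTGAAAGGGTTTCTCTCTAATTTATAAGCGCAGTTGATTTCTATTAGCTTCTCGTGCTCACTTGCCCCATTGACCAGGTAAGCAACCTGCAAGTGAGTGCGACCAAACCAGCGAGGGGACCGTATCAACGGGTTACATGTTAGGACACACAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTCCCGCGCACACATGTCAAGCGCCGAAGACGGGAAAACCGTAGTGGTGACAAGCTAAACCTGCGGT
C115c	C	CCTCCGCTTAAAGGATTTCTCTCTAATTTATAAGCGCAGTTGATTTCTATTAGCTTCTCGTGCTCGCTTGCCCCATTGACCAGGTAAGCAACCTGCAAGTGAGTGCGACCAAACCAGCGAGGGGACCGTATCAACGGGTTACATGTTAGGACACACAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTCCCGCGCACACATGTCAAGCGCCGAAGACGGGAAAACCGGAGTGGTGACAAGCTAAACCTGCGAT
C115b	C	CCTCCGCTGAAAGGATTTCTCTCTAAGTTATAAGCGCAGTTGATTTCTATTAGCGTCTCGTGCTCACTTGCCCCATTGACCAGGTAAGCAACCTGCAAGTGAGTGCGACCAAACCAGCGAGGGGATCGTATCAACGGGTTACATGTTAGGACACACAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTCCCGCGCACACATGTCAAGCGCCGAAGACGGGAAAACCGGAGTGGTGACAAGCTAAACCTGCGGT
C3a	C	CCTCCGCTGAAAGGATTTCTCTCTAATTTATAAGCGCAGTTGATTTCTATTAGCTTCTCGTGCTCACTTGCCCCATTGACCAGGTAAGCAACCTGCAAGTGAGTGCGACCAAACCAGCGAGGGGACCGTATCAATGGGTTACATGTTAGGACACACAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTCCCGCGCACACATGTCAAGCGCCGAAGACGGGAAAACCGGAGTGGTGACAAGCTAAACCTGCGGT
C3ab	C	CCTCCGCTGAAAGGATTTCTCTCTAATTTATAAGCGCAGTTGATTTCTATTAGCTTCTCGTGCTCACTTGCCCCATTGACCTGGTAAGCAACCTGCAAGTGAGTGCGACCAAACCAGCGAGGGGACCGTATCAACGGGTTACATGTTAGGACACACAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTCCCGCGCACACATGTCAAGCGCCGAAGACGGGATAACCGGAGTGGTGACAAGCTAAACCTGCGGT
C1	C	CCTCCGCTGAAAGGATTTCACTCTAATTTATAAGCGCAGTTGATTTCTATTAGCTTCTCGTGCTCACTTGCCCCATTGACCAGGTAAGCAACCTGCAAGTGAGTGCGACCAAACCAGCGAGGGGACCATATCAACGGGTTACATGTTAGGACAGACAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTCCCGCGCACACATGTCAAGCGCCGAAGACGGGAAAACCGGAGTGGTGACAAGCTAAACCTGCGGT
C21	C	CCTCCTCTGAAAGGATTTCTCTCTAATTTATAAGCGCAGTTGATTTCTATTAGCTTCTCGTGCTCACTTGCCCCATTGACCAGGTAACCAACCTGCAAGTGAGTGCGACCAAACCAGCGAGGGGACCGTATCAACGGGTTACATGTTAGGACACACAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTCCCGCGCACACATGTCAAGCGCCGAAGACGGGAAAACCGGAGTGGAGACAAGCTAAACCTGCGGT
C15	C	CCTCGGCTGAACCGATTTCTTTCTAATTTATAAGCGCAGTTGATTTCTATTAGCTACTCGTGCTCACTTGCCCCATTGACCAGGCAAGCAACCTGCAAGTGAGTGCGACCAAACCAGCGTGGGGACCGTATCCACGGGTTACATGTTAGGAAACTCAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTTCCACGCACACATGTCAAGCGCCGAAGACGGGAAAACCGGAGTGGTGACAAGCTAAACCTGCGGT
C15x	C	CCTCGGCTGAACCGATTTCTTTCTAATTTATAAGCGCAGTTGATTTCTATTAGCTACTCGTGCTCACTTGCCCCATTGACCAGGCAAGCAACCTGCAAGTGAGTGCGACCAAACCAGCGTGGGGACCGTATCCACGGGTTACATGTTAGGAAACTCAGCGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTTCCACGCACACATGTCAAGCGCCGAAGACGGGAAAAACGGAGTGGTGACAAGCTAAACCTGCGGT
C15a	C	CCTCGGCTGAACCGATTTCTTTCTAATTTATAAGCGCAGTTGATTTCTATTAGCTACTCGTGCTCACTTGCCCCATTGACCAGGCAAGCAACCTGCAAGTGAGTGCGACCAAACCAGCGTGGGGACCGTATCCACGGCTTACATGTTAGGAAACTCAGTGCGTATGCAGACCTTTATTTCGCCGGGGTATTCTTTTCCACGCACACATGTCAAGCGCCGAAGACGGGAAAACCGGAGTGGTGACAAGCTAAACCTGCGGT
D1	D	TTAGTTTGACAGCCACTTGTATGCGGCGGGATGTGATGAACACGAGGCTGATGTCGAAAGATATTTCTTATGAAGTGGACCGTAGTCAAAGGTCTAAGGAATTGTCGAGTGCGTACTTATAAGCCCGGATATGCACCTCGCAGAGCTTTCACAATTCACCCTGTCCGCGGTCAACGTAAGATCAAGCGATATAGTCACCTGGTTGTTTCATGTCCTAAAGATAGTCTCGATCAGGATAGCCATGAACTCTGAAGAAGCGA
D4	D	TTAGTTTGACAGCCACTTGTATGCGGCGGTATGTGATGAACACGAGGCTGATGTCGAAAGATATTTCTTATGAAGTGGACCGTAGTCAAAGGTCTAAGGAATTGTCGAGTGCGTACTTATAAGCCCGGATATGCACCTCGCAGAGCTTTCACAATTCACCCTGTCCGCGGTCAACGTAAGATCAAGCGATATAGTCACCTGGTTGTTTCATGTCCTAAAGATAGTCTCGATCAGGATAGCCATGAACTCTGAAGAAGCGT
D4c	D	TTAGTTTGACAGCCACTTGTATGCGGCGGGATGTGATAAACACGAAGCTGATGTCGAAAGATATTTCTTATGAAGTGGACCGTAGTCAAAGGTCTAAGGAATTGTCGAGTGCGTACTTATAAGCCCGGATATGCACCTCGCAGAGCTTTCACAATTCACCCTGTCCGCGGTCAACGTAAGATCAAGCGATATAGTCACCTGGTTGTTTCATGTCCTAAAGATAGTCTCGATCAGGATAGCCATGAACTCTGAAGTAGCGA
D1a	D	TTAGTTTGACAGCCACTTGTATGCGGCGGGATGTGATGAACACGAGGCTGATGTCGAAAGATATTTCTTATGAAGTGGACCGTAGTCAAAGGTCTAAGGAATTGTCGAGTGCGTACTTATAAGCCCGGATATGCACCTCGCAGAGCTTTCACAATTCACCCTGTCCGCGGTCAACGTAAGATCAAGCGATATAGTCACCTGGTTGTTTCATGTCCTAAAGATAGTCTCGATCAGGATAGCCATGAACTCTCAAGAAGCGA
A1	A	CCTACTGTTGCCTGTAGAGGAGGAGACAACGGTAGTTCGATTCATAAAGCACACGTGTCTAAACTGGTAACTCTGTGTTCTGCAGCCCAGTTTGACTTACTGACAGTGTGAGCGCCTGCTAAGGTTCCCCGAATTTGGCGGCCAGTCTTGCAAGAGGTGATTATCTCCCTTAAATAAGACTCGGGTCTCTCGTTTATTTCTAGTATATCACAGGGAAGCGCCATAGGTCGGCGCAAGTCCGTCATTGCCCCTGGCCCGCC
A1a	A	CCTACTGTTGCCTGTAGAGGAGGAGACAACGGTAGTTCGATTAATAAAGCACACGTGTCTAAACTGGTAACTCTGTGTTCTGCAGCCCAGTTTGACTTACTGACAGTGTGAGCGCCTGCTAAGGTTCCCCGAATTTGGCGGCCAGTCTTGCAAGAGGTGATTATCTCCCTTAAATAAGACTCGGGTCTCTCGTTTATTTCTAGTATATCACAGGGAAGCGCCATAGGTCGGCGCAAGTCCGTCATTGCCCCTGGCCCGCC
B1	B	ACTCCGTTACCGCAACTAGACGGGTCCGTACTGTTAGGCAGTCATGAGCCAATCCAGCTCGTGCTTGCAGTGTAAGTTGCCCCTTCAAAACCTAGTGGGAGTAATGCCTTCATGTGAGGTTAGCTAGTGCATTCGCGTCGAGTATTGGAGGTCAACCCCGAAATTAATTCGCGTCAAAGTTCTACATCCCCGAGTAGTGACTGTAGTGCAAGTTGTTGCGACAAGTTGTCATAGCAGCAGGGGACTGATTATACAGTTTT
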