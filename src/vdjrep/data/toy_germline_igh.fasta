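>IGHV1-2*01
GAGGCAGGTGTTTTTCAGAACGCCCCGTACCGTAAAATGAGCACCGGTATGGCCAAGCAATCGTGTCTTTCTACTATGAAGCCAAAGTTTTTTTTCAAAATTGAGTGGGATTTATACATATACGACGTTGTCGCTCGTCTAGACAATCCCGGCGATGAATACATGGACTTAAACCATCATTCTAAGACGGCTAACAATCGTTTCCGCGGATTTAATTTTATGAAGTACGAAGCGGTTGTGCGGTTAGGTGGCTACGCCGAGACTATGGAGGCTTGCCACACATACTAC
>IGHV1-69*01
GAGATGGTATCCCAGCACAAAGCAATACCGATGGCAAACGCTGAGGATAACTTGCTACCAGGATGCTTCCACGAGATGTTCGGACCATTTATTGGGCCCGTCGATTGGGCCCCAGAGCGTATTTACCTATTCCCTGGTAAGCATACAGGTCATAAGTACAATTACCATGTCGTTACTTCAATGTTCAATCAGAAAGAGAGTCACAGGCGTAAGCCCTATCCTATTTCACTCATACTAGTCCAGGTTCAAGCTTCGACCAGTTTAGTCGGCGAATGCTTGCATACAGTA
>IGHV2-5*02
GAGCACGTGTTCAAAGGAAACTTCGCAAATATGCGTGTACATCAGAATTACCAGGAACATCAGTGTGAGGGAATTGAAACGTACTTCCCATATGCCGCACACTATTGGTCTACTACGCACAACTCTAAGATGGCAATAATCTACCAAAATTTGGGTCATTCTGGACCGGGTATGACTATATTTCAGAACTCACAGTTCCTTGAGATGCCTAATACAATGCTCCGAGTCGCGAAAAAAGTAACGAAGCAAGTGAGAAATATAAAGACATCGACCTGCTCTGTCCAGATC
>IGHV3-23*01
GAGATGAACCACGGTCCGGTGATCGTTCCCAATGAGTCGGATCCTTTTTACATGGAGGATATGTGCTTCTCTGCAAATTCTATTGTTTTGTCGAAGCAAAAGTTCTGGCCAATTTCGACCCATTTCCCAGAGATAGAGCCAGGAGATAACTTGATAGACGATGGGGGTAAGGAAGGTGCAACTTACGTGCGCCATATGCGCAAGGGAACAGCGTTCCAGGGAACGCATTATTATACGTTGTTCGGCATGTTTGGCGGCCACCCTGAGCAGTCTTGTTACGCACAAAAG
>IGHV4-34*01
GAAATGATACATGGGGACGTCCGAAACCCCTCGAACCAAAAAGACGATGGCTATGAACTAAATTGCAAGCGATATAGTGATGGGAAGGTTATTCTGTTCGTGCTTTGGAATCCACTTTTGCAAACCGTAGGGGGAGTGAAGCAAAGCAAACCGGCGATTGCCAGCCCGGATATAGTGTTCATGCAGGCTCATTTGTCGGACGTGGACCATATACTTAAGGAGAACGATCTGGTTCAGCCGTTCACAACGCCTGTCCAGGACGAGCGCAATAGCTGTCTGCAGGAGATC
>IGHV4-59*01
GAAATTATGCTGTACTATGAATATGCCCAAGATTTAATGTTTGTGATGTACTTCTACAATATGTGTGATATACACCTCCCTTTCGTAAAGCAGTTGAAGGACATGTGGGGCAATTTTAAAAAGGTTAAGCATATATTCATGGTCTATGGCGTCAGTGAACACAATCACAGAGAGGTAGTGAGGCGTACAATTCAGGAACCGTTCCATCTTGTCAACCCTATGGATCGGAAAGAATACCACGACGCGCAATTTTTCGCTCGTATAGAACGCAAATGCACGCCCCCACAA
>IGHV6-1*01
GAGATTATGAACACAGAGATTGACAATTTAGATCACGCAAAATATATACTAATAGTCAAAAATTGCAAATTGGTCTTGGGGCCACAGACGACGTACATGCGCGAGTGGCCACCTAAAATGCCAAGAAACCATAAGAACAGTTTTAAGCAAGTAGAACTTGAGCAAATCATGTATGATGTTCCGGCCCAACGTGGATCGTCTGATGTAGATATCACGAAAGCGGACCAGGACCATCCAACTATAGAACAAAACACGCGGCGCCAACTTAAGAATTGTGGACAAACATTA
>IGHJ1*01
GCCGAGTATTTTTGGGGACAGGGTACCTTGGTAACCGTCTCTTCT
>IGHJ3*02
GACGCCGGCGACTGGGGACAGGGGACCATGGTCACGGTGTCCAGT
>IGHJ4*02
TATGGGGATTATTGGGGTCAGGGAACACTCGTAACCGTGTCTTCA
>IGHJ6*01
TACTATGGGATGTGGGGCAAAGGGACTACCGTTACCGTCTCATCC
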