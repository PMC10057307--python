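>IGKV1-5*01
GACAACGTAGAAGAGTACGAGATGCATTATACTGAAAAGGAACTCCAATTTGGCAACAATGTCCACTGTGAATCCGACATTATGCATTTCGGCACTGGTGATTGGGGTGATTTCATGTATGCTTTTGTAAAAATCCCCCGTTATCGAGTAATCTTTGGTAAATATGATCGATCCCCCTCCCCATTTACTTACTTCAAGTATCGGAATTTCACTCAAACCGAACAAGGACCGTCGAAGCACGCCAAAAATAATCAGAAATATTGTGATATATTTACACATAAAGAT
>IGKV1-39*01
GATGTGGAGAAACTTTCTGTAGCTAACCGTCACCATGTTTATGCTTATGGACGCCCGCACCAAAACTGCTTCCAACAGTTTGGAATCATGGCAGATACGAGTTGGGAATTTCAATACGAAGATGATCAAGAAACTGCGTATGTACGACCGACTGAATCCGGGATCGTTATGATGGTACAAACCATGGTCCGCTTCATCAGCAGAAACGGCTTTCTCCATATCGAAATGATGTACATTGTGTTTGAGGGAATGGACCGTGACTGCCATTACGCCATGGTTCATACT
>IGKV2-28*01
GACACAAATTTTATCAGTAACCGTTTCGCCTTCGATACTCTTATAAGGTCACCGCTGGTAAACATATGCCAAGATATTATAAGACTCAGACAGCCGAATACGTGGAGTGCCGATAAGGACTTATCCTCAATGTCAAGGGGTGCGTCATTACAATACGTCACGCAGTATTCTTTCTTAGAACAGGCACATAATCTGCCGAAACGCTTCTACCTCAGACGTAACGAGATGAATGAGAACAAACGCTCACGTCCCATTGGCAAGTGTGACCATTCATCTGCTCAGTAT
>IGKV2D-29*01
GATGCCGTTCTCCAGCCTATTCGAGGGGTTCATCACGGGCAAATGAAGAAGATGATGCTGCATTTTTGTGGACCTCTCAAGTTTGCCAAAAATCAACTAGCCTGGGGATACGTCGGACTCATGGTCAACGGTGAGATGATGGATATGATGTACGGCAAGTCCCGCGAGGTGAAGAAGCAGCCTGCGTTTGACAATCATCGTCACAAACAAATGCGACCTCAGCTTATTAAGCAAAATGATTTAGGTATGCAGGTAATCGCGTGTCGAGATAGGACGCTGCCTATA
>IGKV3-20*01
GACTTCTCAGGTTTTCTCTATCACATGCACCGAGAGACGGATAAGGTTGGAGAGCTCTTGAGAGAGTGCCACGGAACAAATCAACGCTTCACCAAGGTAGTGTGGGGGGCGATAGTCAAAGGATCCTACTACATGACCAGACCACTTGCTGATCCCATGTCGATGTTCAAAAAGAACAAGGGAATTTACGATATTGCAATTGGGATGATGGACGAGGTGACTTTCAGGAAAATGTATGTCCAAGATTTCGTCAAAAAGTACTGTGGCAGACCTGATGACGGTCCA
>IGKV4-1*01
GACATCGGTTCTATGGAGATTGGGGATCCAGAGGGAGTCGAGACGATTAGTCGACTCGAGGCGTATTGCGGAAAGCCGGATTTCGATATGCGAGCTATAGAGTGGGGTTTGGGAAACGACGAAAATCTACCACCCCATAACGAGTACCTGACGCACATGAGCTCGCCTGAGCAGCTAGGGAGAGAAATCCATGTCGAGATTGTGATAGATATCGCTCACAAGGTAGGTAACACGCTAAACCCCAAAGAGCTAGGCGTTGGCTGCGTAATGCATATGGATAAGCAC
>IGKV5-2*01
GACTTCATAGAAGGCGTCCTGCCGGGACACAAACAGTTCGGACTGAGAAAATTCATCCTCGACAACTGCCAGGAGGAGATCCAGCAACTCACCGCTTTCAAATGGACAATCTTTGCCCATAACCATGACATCGCGAACCCACAGGGGCAGAATATAAAGCCTATTATTCCGGGTAACGAGCAAGTTACTTCGCACTTTTATTACAAACCGGATTATGATAGTCTAAACAGTAATGCGGCTAATTTCTACAAGAGTCAGTCCTGCTTCGAGGTGAAAGAACTTCAG
>IGKJ1*01
CGAACTTTTGGGCAGGGAACAAAAGTAGAAATCAAA
>IGKJ2*01
TACAGCTTCGGTCAGGGAACGAAACTAGAAATTAAA
>IGKJ4*01
TTAACTTTTGGTGGCGGTACGAAAGTTGAGATAAAG
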