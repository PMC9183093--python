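label,count
Actinobacterium sp.,1
Aerococcus viridans,1
Agrobacterium sp.,1
Arthrobacter sp.,2
Bacillus sp.,2
Bosea robiniae,1
Chryseobacterium sp.,1
Curtobacterium sp.,1
Endobacter medicaginis,1
Herbaspirillum robiniae,1
Klebsiella sp.,1
Leifsonia sp.,1
Methylibium sp.,1
Methylobacterium sp.,1
Micromonospora sp.,1
Mycobacterium sp.,1
Novosphingobium sp.,1
Paenibacillus enshidis,1
Paenibacillus sp.,3
Pantoea agglomerans,1
Pantoea sp.,1
Pedobacter panaciterrae,1
Pseudomonas sp.,1
Rahnella sp.,1
Rhizobium sp.,1
Shinella sp.,1
Sinorhizobium sp.,1
Stenotrophomonas rhizophila,1
Stenotrophomonas sp.,1
Streptomyces sp.,1
Tardiphaga robiniae,1
Variovorax sp.,1
Xanthomonas sp.,1
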