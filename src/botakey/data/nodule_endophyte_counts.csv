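label,count
Pseudomonas sp.,16
Bacillus sp.,12
Paenibacillus sp.,10
Bacillus megaterium,9
Enterobacter sp.,7
Bacillus simplex,6
Mesorhizobium sp.,6
Phyllobacterium sp.,6
Erwinia persicina,4
Pantoea ananatis,4
Streptomyces sp.,4
Acinetobacter sp.,3
Agrobacterium sp.,3
Agrobacterium tumefaciens,3
Ancylobacter sp.,3
Enterobacter agglomerans,3
Sphingomonas sp.,3
Staphylococcus pasteuri,3
Xanthomonas sp.,3
Achromobacter sp.,2
Arthrobacter sp.,2
Bacillus subtilis,2
Bacillus thuringiensis,2
Brevibacillus sp.,2
Corynebacterium sp.,2
Dyella sp.,2
Herbaspirillum sp.,2
Inquilinus sp.,2
Kocuria sp.,2
Leifsonia sp.,2
Lysinibacillus sp.,2
Micromonospora lupini,2
Micromonospora saelicesensis,2
Pantoea agglomerans,2
Pantoea sp.,2
Pseudomonas fluorescens,2
Pseudomonas fragi,2
Rhizobium leguminosarum,2
Rhizobium nepotum,2
Rhizobium sp.,2
Sphingobacterium sp.,2
Staphylococcus epidermidis,2
Staphylococcus sp.,2
Stenotrophomonas sp.,2
Variovorax sp.,2
Actinoplanes sp.,1
Agrobacterium rhizogenes,1
Bacillus brevis,1
Bacillus circulans,1
Bacillus flexus,1
Bacillus insolitus,1
Bacillus kochii,1
Bacillus mojavensis,1
Bacillus pumilus,1
Bacillus sporothermodurans,1
Bordetella avium,1
Bosea sp.,1
Brevibacillus agris,1
Burkholderia sp.,1
Buttiauxella sp.,1
Caulobacter sp.,1
Chitinophaga sp.,1
Chryseobacterium sp.,1
Cohnella lupini,1
Cupriavidus sp.,1
Curtobacterium citreum,1
Curtobacterium flaccumfaciens,1
Curtobacterium luteum,1
Delftia sp.,1
Enterobacter cloacae,1
Fontibacillus phaseoli,1
Herbaspirillum lusitanum,1
Kaistia sp.,1
Klebsiella sp.,1
Luteibacter sp.,1
Lysobacter sp.,1
Massilia sp.,1
Micromonospora aurantiaca,1
Micromonospora carbonacea,1
Micromonospora chokoriensis,1
Micromonospora coxiensis,1
Micromonospora halophytica,1
Micromonospora humi,1
Micromonospora krabiensis,1
Micromonospora luteifusca,1
Micromonospora luteiviridis,1
Micromonospora marina,1
Micromonospora matsumotoense,1
Micromonospora mirobrigensis,1
Micromonospora noduli,1
Micromonospora phytophila,1
Micromonospora pisi,1
Micromonospora purpureochromogenes,1
Micromonospora rifamycinica,1
Micromonospora siamesi,1
Micromonospora sp.,1
Micromonospora ureilytica,1
Micromonospora vinacea,1
Mucilaginibacter sp.,1
Mycobacterium sp.,1
Novosphingobium sp.,1
Ochrobactrum ciceri,1
Ochrobactrum sp.,1
Oerskovia sp.,1
Ornithinicoccus sp.,1
Paenibacillus sp.,1
Paenibacillus endophyticum,1
Paenibacillus kribbensis,1
Paenibacillus lupini,1
Paenibacillus polymixa,1
Paraburkholderia nodosa,1
Paracoccus sp.,1
Phyllobacterium endophyticum,1
Phyllobacterium ifriquiensis,1
Phyllobacterium loti,1
Phyllobacterium myrsinacearum,1
Promicromonospora sp.,1
Providencia sp.,1
Pseudomonas brassicacearum,1
Pseudomonas brenneri,1
Pseudomonas corrugata,1
Pseudomonas frederiksbergensis,1
Pseudomonas putida,1
Pseudomonas rhodesiae,1
Pseudomonas yamanorum,1
Rahnella aquatilis,1
Rahnella sp.,1
Ralstonia pickettii,1
Rhizobium hidalgonense,1
Rhizobium radiobacter,1
Rhizobium vignae,1
Rhodococcus sp.,1
Serratia liquefaciens,1
Serratia plymuthica,1
Serratia proteamaculans,1
Starkeya novella,1
Stenotrophomonas sp.,1
Stenotrophomonas maltophilia,1
Streptomyces sp.,1
Streptomyces ciscaucasicus,1
Thiobacillus sp.,1
Variovorax paradoxus,1
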