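label,count
Rhizobium,82
Ensifer,2
Microvirga,2
Pararhizobium,2
Mesorhizobium,62
Agrobacterium,2
Paenibacillus,1
Pseudomonas,1
Bradyrhizobium,45
Sinorhizobium,32
Neorhizobium,6
Phyllobacterium,3
Burkholderia,1
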