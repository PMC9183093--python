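former_name,current_name
Hedysarum spinosissimum,Sulla spinosissima
Hedysarum glomeratum,Sulla capitata
Hedysarum coronarium,Sulla coronaria
Biserrula pelecinus,Astragalus pelecinus
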