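label,count
Anagyris foetida,4
Astragalus boeticus,1
Astragalus hamosus,1
Astragalus pelecinus,16
Astragalus terraccianoi,14
Bituminaria bituminosa,4
Ceratonia siliqua,3
Cicer arietinum,18
Colutea arborescens,8
Coronilla valentina,1
Cytisus laniger,9
Cytisus scoparius,16
Cytisus spinosus,3
Cytisus villosus,3
Dorycnium hirsutum,1
Ervilia hirsuta,9
Ervum tetraspermum,3
Genista monspessulana,1
Glycyrrhiza glabra,6
Hippocrepis multisiliquosa,2
Hippocrepis unisiliquosa,4
Hymenocarpos circinnatus,1
Lathyrus aphaca,1
Lathyrus clymenum,1
Lathyrus latifolius,6
Lathyrus pratensis,5
Lens culinaris,4
Lotus angustissimus,1
Lotus conimbricensis,1
Lotus corniculatus,21
Lotus cytisoides,1
Lotus edulis,1
Lotus maritimus,1
Lotus ornithopodioides,1
Lotus parviflorus,11
Lotus subbiflorus,1
Lotus tenuis,3
Lotus tetragonolobus,10
Lotus uliginosus,1
Lupinus albus,3
Lupinus angustifolius,4
Lupinus luteus,1
Lupinus micranthus,6
Medicago arabica,1
Medicago ciliaris,1
Medicago doliata,1
Medicago hispida,7
Medicago intertexta,1
Medicago litoralis,1
Medicago lupulina,1
Medicago murex,1
Medicago orbicularis,3
Medicago praecox,1
Medicago rigidula,1
Medicago rugosa,2
Medicago sativa,21
Medicago scutellata,1
Medicago tenoreana,1
Medicago tornata,1
Medicago truncatula,4
Medicago turbinata,1
Melilotus italicus,1
Ononis natrix,1
Ononis ornithopodioides,1
Ononis spinosa,2
Ornithopus compressus,5
Ornithopus perpusillus,6
Ornithopus pinnatus,5
Phaseolus vulgaris,43
Pisum sativum,31
Robinia pseudoacacia,19
Scorpiurus muricatus,11
Scorpiurus vermiculatus,1
Spartium junceum,3
Sulla capitata,10
Sulla coronaria,7
Sulla spinosissima,16
Trifolium campestre,1
Trifolium diffusum,1
Trifolium dubium,1
Trifolium fragiferum,4
Trifolium nigrescens,1
Trifolium ornithopodioides,1
Trifolium pratense,22
Trifolium repens,13
Trifolium strictum,1
Trifolium suffocatum,1
Trifolium tomentosum,4
Trigonella elegans,1
Trigonella maritima,1
Trigonella monspeliaca,1
Trigonella officinalis,1
Trigonella sicula,1
Trigonella smalii,6
Vicia disperma,1
Vicia faba,19
Vicia lathyroides,2
Vicia leucantha,1
Vicia nigricans,2
Vicia peregrina,1
Vicia sativa,1
Vicia sepium,2
Vicia villosa,1
Vigna unguiculata,28
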