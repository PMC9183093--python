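label,count
Agrobacterium sp.,1
Agrobacterium tumefaciens,1
Bradyrhizobium canariense,8
Bradyrhizobium cytisi,2
Bradyrhizobium elkanii,4
Bradyrhizobium japonicum,7
Bradyrhizobium liaoningense,2
Bradyrhizobium lupini,2
Bradyrhizobium rifense,2
Bradyrhizobium sp.,17
Bradyrhizobium yuanmingense,1
Burkholderia sp.,1
Ensifer sp.,2
Mesorhizobium abyssinicae,1
Mesorhizobium albiziae,1
Mesorhizobium amorphae,2
Mesorhizobium australicum,1
Mesorhizobium chacoense,3
Mesorhizobium ciceri,4
Mesorhizobium erdmani,1
Mesorhizobium huakuii,4
Mesorhizobium intechi,1
Mesorhizobium japonicum,2
Mesorhizobium jarvisii,1
Mesorhizobium loti,10
Mesorhizobium mediterraneum,3
Mesorhizobium muleiense,1
Mesorhizobium opportunistum,1
Mesorhizobium plurifarium,1
Mesorhizobium robiniae,1
Mesorhizobium shonense,1
Mesorhizobium sp.,16
Mesorhizobium temperatum,2
Mesorhizobium thiogangeticum,1
Mesorhizobium tianshanense,3
Mesorhizobium wenxinie,1
Microvirga sp.,2
Neorhizobium galegae,2
Neorhizobium huautlense,2
Neorhizobium sp.,2
Paenibacillus sp.,1
Pararhizobium giardinii,2
Phyllobacterium myrsinacearum,2
Phyllobacterium sp.,1
Pseudomonas sp.,1
Rhizobium acidisoli,2
Rhizobium aethiopicum,1
Rhizobium anhuiense,3
Rhizobium cellulosilyticum,1
Rhizobium chutanense,1
Rhizobium etli,4
Rhizobium gallicum,3
Rhizobium hidalgonense,2
Rhizobium indicum,1
Rhizobium indigoferae,2
Rhizobium laguerreae,4
Rhizobium leguminosarum,21
Rhizobium leucaenae,1
Rhizobium lusitanum,1
Rhizobium mesosinicum,1
Rhizobium multihospitium,1
Rhizobium phaseoli,3
Rhizobium pisi,3
Rhizobium rhizogenes,1
Rhizobium ruizarguesonis,1
Rhizobium sophorae,2
Rhizobium sp.,20
Rhizobium sullae,2
Rhizobium tropici,1
Rhizobium vallis,1
Sinorhizobium fredii,3
Sinorhizobium medicae,5
Sinorhizobium meliloti,20
Sinorhizobium sp.,4
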