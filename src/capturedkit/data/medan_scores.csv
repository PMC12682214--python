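scientific_name,count,concealability,abundance,habitat_access,focal_island,removability,teeth_removal,success_in_captivity,multiple_uses,enjoyability,ecological_value,conservation_value,symbolic_value
Macaca fascicularis,774,4,5,7,1,5,0,3,1,6,1,1,0
Nycticebus coucang,714,3,3,6,1,2,1,3,1,5,1,3,0
Macaca nemestrina,380,3,3,6,1,5,0,3,1,5,1,3,0
Trachypithecus cristatus,65,3,4,2,1,4,0,3,1,5,1,2,1
Presbytis thomasi,7,2,3,2,1,4,0,3,0,5,0,4,1
Presbytis melalophos,4,3,2,2,1,4,0,4,0,5,0,5,1
Trachypithecus auratus,3,2,3,2,0,4,0,3,0,5,0,4,1
Hylobates agilis,3,2,2,2,1,4,1,2,0,5,0,4,1
Symphalangus syndactylus,2,1,2,2,1,4,1,3,0,4,0,4,0
Hylobates lar,1,2,2,2,1,4,1,2,0,5,0,4,1
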