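scientific_name,common_name,mean_body_mass_kg,legally_trappable,threat_status,iucn_status_2022,population_trend,habitats_major_importance,on_focal_island,endemic_to_focal_country,locomotion,diel,group_living,trophic_guild,teeth_removed_in_trade,n_markets_found,uses_after_purchase,age_group_traded,average_price,ecological_value,symbolic_value
Macaca fascicularis,long-tailed macaque,4.5,true,LC,EN,decreasing,wetland;forest;anthropogenic,true,false,both,diurnal,true,frugivore,false,,pet;food,mostly_nonadults,,true,false
Nycticebus coucang,greater slow loris,0.65,false,VU,EN,decreasing,forest;anthropogenic,true,false,arboreal,nocturnal,false,omnivore,true,,pet;medicine,equal_mix,,true,false
Macaca nemestrina,pig-tailed macaque,8.8,true,VU,EN,decreasing,forest;anthropogenic,true,false,both,diurnal,true,frugivore,false,,pet;food,mostly_nonadults,,true,false
Trachypithecus cristatus,silvered leaf monkey,6.3,true,NT,VU,decreasing,forest,true,false,arboreal,diurnal,true,folivore,false,,pet;food,mostly_nonadults,,true,true
Presbytis thomasi,Thomas's leaf monkey,6.7,false,VU,VU,decreasing,forest,true,true,arboreal,diurnal,true,folivore,false,,pet,mostly_nonadults,,false,true
Presbytis melalophos,Sumatran leaf monkey,6.5,true,EN,EN,decreasing,forest,true,true,arboreal,diurnal,true,folivore_frugivore,false,,pet,mostly_nonadults,,false,true
Trachypithecus auratus,ebony leaf monkey,6.3,false,VU,VU,decreasing,forest,false,true,arboreal,diurnal,true,folivore,false,,pet,mostly_nonadults,,false,true
Hylobates agilis,agile gibbon,5.7,false,EN,EN,decreasing,forest,true,false,arboreal,diurnal,true,frugivore,true,,pet,mostly_nonadults,,false,true
Symphalangus syndactylus,siamang,11.3,false,EN,EN,decreasing,forest,true,false,arboreal,diurnal,true,folivore_frugivore,true,,pet,mostly_nonadults,,false,false
Hylobates lar,white-handed gibbon,5.5,false,EN,EN,decreasing,forest,true,false,arboreal,diurnal,true,frugivore,true,,pet,mostly_nonadults,,false,true
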