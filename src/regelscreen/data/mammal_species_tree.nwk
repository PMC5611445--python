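(Ornithorhynchus_anatinus,((Monodelphis_domestica,(Macropus_eugenii,Sarcophilus_harrisii))Marsupialia,(((Dasypus_novemcinctus,(Choloepus_hoffmanni,Mylodon_darwinii)Pilosa)Xenarthra,((Orycteropus_afer,(Elephantulus_edwardii,(Chrysochloris_asiatica,Echinops_telfairi)Afrosoricida))Afroinsectiphilia,(Procavia_capensis,((Loxodonta_africana,(Elephas_maximus,Mammuthus_primigenius))Elephantidae,(Trichechus_manatus_latirostris,(Dugong_dugon,Hydrodamalis_gigas))Sirenia)Tethytheria)Paenungulata)Afrotheria)Atlantogenata,(((Erinaceus_europaeus,(Sorex_araneus,Condylura_cristata))Eulipotyphla,(((((Pteropus_alecto,Pteropus_vampyrus),(Rousettus_aegyptiacus,Eidolon_helvum))Pteropodidae,(Megaderma_lyra,((Rhinolophus_ferrumequinum,Rhinolophus_sinicus),Hipposideros_armiger))Rhinolophoidea)Yinpterochiroptera,(Miniopterus_natalensis,(Eptesicus_fuscus,(Myotis_brandtii,(Myotis_davidii,Myotis_lucifugus)))Vespertilionidae)Yangochiroptera)Chiroptera,(((Manis_javanica,Manis_pentadactyla)Pholidota,((Felis_catus,(Acinonyx_jubatus,(Panthera_pardus,(Panthera_tigris_altaica,Panthera_uncia))))Felidae,((Canis_lupus_familiaris,Lycaon_pictus)Canidae,((Ailuropoda_melanoleuca,Ursus_maritimus)Ursidae,((Odobenus_rosmarus,Leptonychotes_weddellii)Pinnipedia,Mustela_putorius_furo)))Caniformia)Carnivora)Ferae,(((Equus_asinus,(Equus_caballus,Equus_przewalskii))Equidae,(Tapirus_indicus,((Dicerorhinus_sumatrensis,Coelodonta_antiquitatis),(Rhinoceros_unicornis,(Ceratotherium_simum,Diceros_bicornis)))Rhinocerotidae)Ceratomorpha)Perissodactyla,(((Camelus_dromedarius,Camelus_ferus),Vicugna_pacos)Camelidae,((Sus_scrofa,(Sus_cebrifrons,Sus_verrucosus))Suidae,(((Giraffa_camelopardalis,Okapia_johnstoni)Giraffidae,(Capreolus_capreolus,((((Bos_taurus,Bos_indicus),(Bos_grunniens,Bison_bison)),Bubalus_bubalis)Bovina,((Capra_aegagrus,Capra_hircus),(Ovis_aries,Pantholops_hodgsonii))Caprinae)Bovidae))Ruminantia,((Balaena_mysticetus,(Balaenoptera_physalus,(Balaenoptera_acutorostrata,Balaenoptera_bonaerensis)))Mysticeti,(Physeter_macrocephalus,(Lipotes_vexillifer,(Orcinus_orca,Tursiops_truncatus)Delphinidae))Odontoceti)Cetacea)Cetruminantia)Artiofabula)Artiodactyla)Euungulata)Fereuungulata)Scrotifera)Laurasiatheria,(((Oryctolagus_cuniculus,Ochotona_princeps)Lagomorpha,((Marmota_marmota,Spermophilus_tridecemlineatus)Sciuridae,((Dipodomys_ordii,(Jaculus_jaculus,(Nannospalax_galili,(((Mesocricetus_auratus,Cricetulus_griseus),((Peromyscus_maniculatus,Neotoma_lepida),(Myodes_glareolus,((Microtus_agrestis,Microtus_ochrogaster),(Ellobius_lutescens,Ellobius_talpinus)))Arvicolinae))Cricetidae,((Mus_musculus,Mus_spretus),(Apodemus_sylvaticus,Rattus_norvegicus))Muridae))Muroidea))Myomorpha,((Heterocephalus_glaber,Fukomys_damarensis)Bathyergidae,(Chinchilla_lanigera,(Octodon_degus,(Cavia_aperea,Cavia_porcellus)Caviidae)))Hystricomorpha))Rodentia)Glires,((Tupaia_belangeri_chinensis,Galeopterus_variegatus),((Otolemur_garnettii,(Daubentonia_madagascariensis,(Propithecus_coquereli,(Microcebus_murinus,(Eulemur_flavifrons,Eulemur_macaco)))))Strepsirrhini,(Tarsius_syrichta,(((Callithrix_jacchus,Cebus_capuchinis),(Saimiri_boliviensis,Aotus_nancymaae))Platyrrhini,(((((Macaca_fascicularis,(Macaca_mulatta,Macaca_nemestrina))Macaca,(Papio_anubis,(Mandrillus_leucophaeus,Cercocebus_atys)))Papionini,Chlorocebus_sabaeus)Cercopithecinae,(Colobus_angolensis,(Nasalis_larvatus,(Rhinopithecus_bieti,Rhinopithecus_roxellana)))Colobinae)Cercopithecoidea,(Nomascus_leucogenys,(Pongo_abelii,(Gorilla_gorilla_gorilla,(Homo_sapiens,(Pan_paniscus,Pan_troglodytes)))))Hominoidea)Catarrhini)Simiiformes)Haplorhini)Primates)Euarchonta)Euarchontoglires)Boreoeutheria)Eutheria)Theria)Mammalia;
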