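taxon	host_group	niche
Alcedoecus alatoclypeatus	Alcidinidae	head
Alcedoffula duplicata	Alcidinidae	generalist
Anaticola crassicornis	Anseriformes	wing
Anatoecus icterodes	Anseriformes	head
Quadraceps punctata	Charadriiformes	generalist
Saemundssonia lari	Charadriiformes	head
Ardeicola expallidus	Ciconiiformes	wing
Ibidoecus bisignatus	Ciconiiformes	head
Campanulotes compar	Columbiformes	body
Coloceras sp	Columbiformes	body
Columbicola columbae	Columbiformes	wing
Cuculicola atopus	Cuculiformes	generalist
Vernoniella bergi	Cuculiformes	generalist
Craspedorrhynchus hirsutus	Falconiformes	head
Degeeriella carruthi	Falconiformes	generalist
Falcolipeurus marginalis	Falconiformes	wing
Chelopistes sp	Galliformes	body
Goniocotes chrysocephalus	Galliformes	body
Oxylipeurus chiniri	Galliformes	wing
Incidifrons transpositus	Gruiformes	head
Meropoecus sp	Meropidae	head
Meropsiella sp	Meropidae	generalist
Osculotes curta	Opisthocomidae	body
Pessoaiella absita	Opisthocomidae	generalist
Brueelia ornatissima	Passeriformes	generalist
Sturnidoecus sp	Passeriformes	head
Pectinopygus bassani	Pelecaniformes	wing
Picicola porisma	Piciformes	generalist
Docophoroides brevis	Procellariiformes	head
Harrisoniella densa	Procellariiformes	wing
Forficuloecus palmai	Psittaciformes	head
Psittaconirmus forficuloides	Psittaciformes	wing
Psittoecus eos	Psittaciformes	body
Strigiphilus crucigerus	Strigiformes	head
Struthiolipeurus nandu	Struthioniformes	generalist
Discocorpus mexicanus	Tinamiformes	body
Pseudolipeurus similis	Tinamiformes	wing
Pseudophilopterus hirsutus	Tinamiformes	head
Strongylocotes orbicularis	Tinamiformes	body
Bovicola bovis	Mammals	
Felicola subrostratus	Mammals	
Stachiella larseni	Mammals	
Trichodectes octomaculatus	Mammals	
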