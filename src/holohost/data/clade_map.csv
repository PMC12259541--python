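host_family,clade
Asteraceae,eudicot
Fabaceae,eudicot
Euphorbiaceae,eudicot
Fagaceae,eudicot
Lamiaceae,eudicot
Malvaceae,eudicot
Rosaceae,eudicot
Rubiaceae,eudicot
Amaranthaceae,eudicot
Apiaceae,eudicot
Brassicaceae,eudicot
Solanaceae,eudicot
Moraceae,eudicot
Betulaceae,eudicot
Salicaceae,eudicot
Ericaceae,eudicot
Cistaceae,eudicot
Plantaginaceae,eudicot
Caryophyllaceae,eudicot
Polygonaceae,eudicot
Ranunculaceae,eudicot
Geraniaceae,eudicot
Boraginaceae,eudicot
Apocynaceae,eudicot
Vitaceae,eudicot
Anacardiaceae,eudicot
Sapindaceae,eudicot
Rutaceae,eudicot
Myrtaceae,eudicot
Oleaceae,eudicot
Poaceae,monocot
Cyperaceae,monocot
Orchidaceae,monocot
Arecaceae,monocot
Liliaceae,monocot
Asparagaceae,monocot
Juncaceae,monocot
Magnoliaceae,other_angiosperm
Lauraceae,other_angiosperm
Annonaceae,other_angiosperm
Piperaceae,other_angiosperm
Nymphaeaceae,other_angiosperm
Pinaceae,gymnosperm
Cupressaceae,gymnosperm
Taxaceae,gymnosperm
Ephedraceae,gymnosperm
Dryopteridaceae,fern_lycopod
Pteridaceae,fern_lycopod
Lycopodiaceae,fern_lycopod
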