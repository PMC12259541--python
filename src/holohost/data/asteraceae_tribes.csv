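host_genus,tribe
Artemisia,Anthemideae
Achillea,Anthemideae
Anthemis,Anthemideae
Tanacetum,Anthemideae
Chrysanthemum,Anthemideae
Inula,Inuleae
Helichrysum,Inuleae
Pulicaria,Inuleae
Dittrichia,Inuleae
Aster,Astereae
Erigeron,Astereae
Solidago,Astereae
Baccharis,Astereae
Helianthus,Heliantheae
Ambrosia,Heliantheae
Xanthium,Heliantheae
Senecio,Senecioneae
Jacobaea,Senecioneae
Centaurea,Cardueae
Cirsium,Cardueae
Carduus,Cardueae
Carthamus,Cardueae
Vernonia,Vernonieae
Eupatorium,Eupatorieae
Mutisia,Mutisieae
Lactuca,Cichorieae
Taraxacum,Cichorieae
Crepis,Cichorieae
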