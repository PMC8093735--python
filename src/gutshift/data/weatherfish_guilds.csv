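category,guild
Detritus,DE
Copepoda,PL
Cladocera-Chydoridae,PL
Cladocera-others,PL
Ostracoda,BE
Oligochaeta,BE
Trichoptera,EP
Asellus aquaticus,EP_BE
Ephemeroptera,EP
Zygoptera,EP
Coleoptera larvae,EP
Coleoptera imagines,EP
Gastropoda,EP
Hirudinea,EP_BE
Podura aquatica,PL
Diptera-not Chironomidae,BE
Heteroptera,EP
Hydrachnellae,EP
others,others
Chironomidae-Prodiamesinae,BE
Chironomidae-Tanypodinae,EP_BE
Chironomidae-Orthocladiinae,EP
Chironomidae-Chironomini,BE
Chironomidae-Tanytarsini,EP_BE
Chironomidae-pupa,PL
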