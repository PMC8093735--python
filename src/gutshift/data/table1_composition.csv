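category,guild,w_mean_juvenile,w_sd_juvenile,w_cv_juvenile,fo_juvenile,iri_juvenile,w_mean_mature,w_sd_mature,w_cv_mature,fo_mature,iri_mature
Detritus,DE,4.00,5.93,148.22,54.55,2.71,20.77,23.35,112.41,100.00,24.65
Copepoda,PL,29.22,16.61,56.85,87.88,42.45,17.86,11.62,65.10,100.00,22.27
Cladocera-Chydoridae,PL,5.70,6.38,112.00,84.85,9.04,1.09,1.99,181.90,73.08,0.57
Cladocera-others,PL,0.03,0.11,404.25,6.06,0.00,0.44,2.13,487.17,7.69,0.10
Ostracoda,BE,3.29,3.57,108.66,81.82,4.90,3.69,3.48,94.17,92.31,3.40
Oligochaeta,BE,3.18,17.39,546.56,12.12,0.06,6.12,18.11,296.12,15.38,2.48
Trichoptera,EP,0.21,0.64,300.99,15.15,0.06,0.66,2.73,413.33,11.54,0.03
Asellus aquaticus,EP_BE,19.33,21.33,110.33,84.85,16.30,16.54,12.68,76.62,92.31,21.65
Ephemeroptera,EP,0.47,1.37,293.36,12.12,0.16,0.23,0.84,357.83,7.69,0.03
Zygoptera,EP,0.10,0.60,574.46,3.03,0.00,,,,,
Coleoptera larvae,EP,6.37,8.57,134.54,72.73,6.82,2.99,3.96,132.48,57.69,2.24
Coleoptera imagines,EP,,,,,,0.12,0.62,509.90,3.85,0.01
Gastropoda,EP,4.52,6.72,148.80,69.70,4.89,2.33,4.06,174.24,53.85,1.55
Hirudinea,EP_BE,0.03,0.15,574.46,3.03,0.00,1.25,6.35,509.90,3.85,0.18
Podura aquatica,PL,0.00,0.03,574.46,3.03,0.00,,,,,
Diptera-not Chironomidae,BE,1.14,6.00,530.00,6.06,0.06,0.23,1.18,509.90,3.85,0.01
Heteroptera,EP,0.00,0.22,400.45,6.06,0.01,0.28,1.05,382.04,7.69,0.01
Hydrachnellae,EP,0.05,0.14,272.16,18.18,0.03,0.04,0.10,248.39,15.38,0.01
others,others,5.25,17.37,330.60,51.52,1.52,0.56,1.50,270.22,26.92,0.21
Chironomidae-Prodiamesinae,BE,0.09,0.33,352.59,9.09,0.02,,,,,
Chironomidae-Tanypodinae,EP_BE,1.89,3.08,162.64,51.52,1.62,11.97,9.77,81.63,84.62,11.81
Chironomidae-Orthocladiinae,EP,6.40,7.86,122.90,69.70,6.15,2.58,2.48,96.14,80.77,2.56
Chironomidae-Chironomini,BE,4.87,6.00,124.25,72.73,4.83,9.14,6.16,67.33,88.46,9.33
Chironomidae-Tanytarsini,EP_BE,2.73,4.72,172.70,69.70,2.18,0.82,1.22,148.79,53.85,0.50
Chironomidae-pupa,PL,0.24,0.99,408.68,6.06,0.01,0.29,1.07,369.53,11.54,0.02
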