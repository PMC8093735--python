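category,avg_dissim,contribution_pct,cumulative_pct,mean_juvenile,mean_mature
Copepoda,9.63,15.73,15.73,30.10,17.90
Detritus,9.23,15.06,30.79,4.00,20.80
Asellus aquaticus,8.52,13.91,44.69,19.00,16.50
Chironomidae-Tanypodinae,5.48,8.95,53.64,1.89,12.00
Oligochaeta,4.44,7.25,60.89,3.18,6.12
Chironomidae-Chironomini,3.72,6.08,66.90,5.03,9.14
Coleoptera larvae,3.11,5.08,72.04,6.37,2.99
Chironomidae-Orthocladiinae,2.95,4.82,76.86,6.40,2.58
Cladocera-Chydoridae,2.81,4.59,81.45,5.98,1.09
others,2.68,4.38,85.82,5.22,0.56
Gastropoda,2.50,4.09,89.91,4.46,2.33
Ostracoda,1.89,3.08,92.99,3.23,3.69
Chironomidae-Tanytarsini,1.39,2.27,95.26,2.89,0.82
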