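food_type,guild,w_mean_juvenile,w_sd_juvenile,w_cv_juvenile,fo_juvenile,iri_juvenile,w_mean_mature,w_sd_mature,w_cv_mature,fo_mature,iri_mature
Detritus,DE,4.13,5.98,144.96,56.25,2.33,20.77,23.35,112.41,100.00,18.81
Benthic,BE,29.20,25.32,86.74,100.00,23.43,27.42,18.92,68.99,100.00,34.02
Epiphytic,EP,21.69,13.60,62.87,87.50,22.25,10.21,8.23,80.66,88.46,8.15
Epiphytic/Benthic,EP_BE,6.04,7.14,118.21,68.75,4.93,21.32,14.49,67.94,92.31,19.66
Planktonic,PL,38.87,19.32,49.70,90.63,47.04,20.23,14.02,69.32,100.00,19.35
others,others,0.07,0.28,389.49,12.50,0.00,0.05,0.16,338.48,11.54,0.01
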