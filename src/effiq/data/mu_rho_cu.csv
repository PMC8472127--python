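# Mass attenuation coefficient of copper (NIST tabulation), density 8.96 g/cm^3.
energy_keV,mu_over_rho_cm2_per_g
10,215.9
15,74.05
20,33.79
30,10.92
40,4.862
50,2.613
60,1.593
80,0.763
100,0.4584
150,0.2217
200,0.1559
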