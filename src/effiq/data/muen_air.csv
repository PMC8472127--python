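# Mass energy-absorption coefficient of dry air, transcribed from the
# standard NIST tabulation (Hubbell & Seltzer); log-log interpolable.
energy_keV,muen_over_rho_cm2_per_g
10,4.742
15,1.334
20,0.5389
30,0.1537
40,0.06833
50,0.04098
60,0.03041
80,0.02407
100,0.02325
150,0.02496
200,0.02672
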