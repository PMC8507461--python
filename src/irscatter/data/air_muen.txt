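# Mass energy-absorption coefficient of dry air (near sea level),
# standard reference tabulation (NIST / ICRU grid values).
# Used to convert photon fluence to air kerma: K = Phi * E * (muen/rho).
# E_keV muen_over_rho_cm2_per_g
10.0 4.742
15.0 1.334
20.0 0.5389
30.0 0.1537
40.0 0.06833
50.0 0.04098
60.0 0.03041
80.0 0.02407
100.0 0.02325
150.0 0.02496
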