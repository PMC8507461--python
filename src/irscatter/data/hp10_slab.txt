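# Personal dose equivalent Hp(10) per unit photon fluence, ICRU slab
# phantom, normal (0 deg) incidence.  Assembled as Hp(10)/Ka slab
# conversion coefficients (ICRP 74 / ISO 4037 style, normal incidence)
# multiplied by the air kerma per fluence E*(muen/rho)_air on the same
# grid (see air_muen.txt).  Backscatter from the wearer's body is
# implicit in the slab-phantom definition of the quantity.
# E_keV hp10_per_fluence_pSv_cm2
10.0 0.0684
15.0 0.8464
20.0 1.0551
30.0 0.8215
40.0 0.6525
50.0 0.5798
60.0 0.5531
80.0 0.5871
100.0 0.6746
150.0 0.9652
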