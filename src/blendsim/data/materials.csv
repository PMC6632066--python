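name,d10_um,d50_um,d90_um,density_g_cm3,poisson,shear_modulus_pa,surface_energy,e_pp,e_pw,mus_pp,mus_pw,mur_pp,mur_pw,mass_fraction
amlodipine besylate,2.74,10.50,28.70,1.36,0.25,1e7,0.00,0.20,0.20,0.50,0.50,0.50,0.50,0.06935
SMCC 90,29.71,106.48,223.88,1.61,0.25,1e7,0.00,0.30,0.50,0.40,0.40,0.20,0.30,0.77065
PVP K25,22.51,62.62,119.75,1.21,0.30,1e7,0.00,0.30,0.50,0.40,0.40,0.25,0.30,0.045
CCM-Na,23.39,50.48,118.28,1.61,0.30,1e7,0.00,0.30,0.50,0.40,0.50,0.30,0.30,0.10
St-Mg,1.09,5.52,24.99,1.11,0.30,1e7,0.02,0.30,0.30,0.50,0.50,0.45,0.40,0.015
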