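# Approximate absorption spectra of the four clinical chromophores used for
# constrained linear unmixing, tabulated 700-970 nm in 10 nm steps.
# Values compiled (with linear smoothing) from standard literature sources:
# hemoglobin molar extinction after the Prahl compilation (cm^-1/M, scaled
# by 1e-3), water absorption after Hale & Querry (cm^-1), lipid absorption
# after van Veen et al. (cm^-1).  Intended for qualitative spectral
# decomposition; not a metrological reference.
wavelength_nm,hb,hbo2,water,lipid
700,1.794,0.290,0.0060,0.0009
710,1.540,0.314,0.0072,0.0011
720,1.327,0.348,0.0104,0.0014
730,1.102,0.390,0.0210,0.0016
740,1.116,0.446,0.0270,0.0018
750,1.405,0.518,0.0260,0.0021
760,1.549,0.586,0.0250,0.0026
770,1.312,0.650,0.0240,0.0028
780,1.075,0.710,0.0230,0.0030
790,0.891,0.774,0.0225,0.0032
800,0.762,0.816,0.0220,0.0035
810,0.717,0.864,0.0232,0.0040
820,0.694,0.916,0.0280,0.0046
830,0.693,0.974,0.0330,0.0055
840,0.693,1.022,0.0430,0.0070
850,0.691,1.058,0.0450,0.0090
860,0.710,1.104,0.0480,0.0120
870,0.750,1.136,0.0510,0.0170
880,0.781,1.168,0.0550,0.0250
890,0.812,1.190,0.0600,0.0390
900,0.870,1.198,0.0680,0.0620
910,0.920,1.216,0.0900,0.1050
920,0.966,1.282,0.1100,0.2100
930,1.005,1.310,0.1700,0.3500
940,1.026,1.346,0.2700,0.2400
950,1.050,1.360,0.3900,0.1100
960,1.056,1.370,0.4500,0.0550
970,1.060,1.380,0.4700,0.0380
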