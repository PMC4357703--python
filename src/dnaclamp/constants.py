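"""Physical constants and package-wide defaults.

All mechanical quantities use the single-molecule convention:
forces in pN, lengths in nm, energies in pN*nm (1 kBT at 298 K = 4.114 pN*nm).
"""

#: Thermal energy at 298 K in pN*nm.
KBT_298 = 4.114

#: Gas constant in kcal/(mol*K), used to convert nearest-neighbor tables.
R_KCAL = 1.9872e-3

#: Rise per base pair of B-DNA duplex, nm.
BP_RISE = 0.34

#: Contour-length gain per bound bis-intercalator, nm (two intercalated
#: moieties, each lengthening the duplex by one base-pair rise).
DELTA_L0 = 2.0 * BP_RISE

#: Marko-Siggia polynomial correction coefficients alpha_2..alpha_7
#: (Bouchiat et al. improved interpolation of the worm-like chain).
WLC_ALPHA = (-0.5164228, -2.737418, 16.07497, -38.87607, 39.49944, -14.17718)

#: Default ssDNA freely-jointed-chain parameters at ~100 mM monovalent salt:
#: Kuhn length (nm), contour per base (nm), stretch modulus (pN).
SSDNA_KUHN = 1.35
SSDNA_CONTOUR_PER_BASE = 0.59
SSDNA_STRETCH = 800.0

#: Default dsDNA elastic parameters for handles / naked DNA.
DSDNA_LP = 48.0
DSDNA_S = 1200.0
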