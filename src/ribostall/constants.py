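"""Physical constants used throughout the package.

Fixed (not configurable) so that printed unit conversions are reproducible.
"""

#: Boltzmann constant in pN·nm/K.
KB_PN_NM_PER_K = 0.0138065

#: Avogadro's number, 1/mol.
N_AVOGADRO = 6.02214e23

#: Thermochemical calorie convention: 1 kcal = 4184 J.
J_PER_KCAL = 4184.0

#: 1 kcal/mol expressed as pN·nm per molecule (1 pN·nm = 1e-21 J).
PN_NM_PER_KCAL_PER_MOL = J_PER_KCAL / N_AVOGADRO * 1e21

#: Distance between A- and P-site mRNA codons from crystal structures, nm.
CODON_STEP_NM = 1.48
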