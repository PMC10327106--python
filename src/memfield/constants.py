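"""Physical constants and unit conventions used throughout the package.

Unit system
-----------
length          angstrom (Å)
charge          elementary charge (e)
charge density  e / Å^3
potential       volt (V)
energy          kcal/mol (REU-equivalent for the reduced composite score)
"""

#: Coulomb prefactor 1/(4*pi*eps0) expressed in V·Å/e.  A unit point charge
#: produces a potential of COULOMB_V_ANG / r volts at a distance r angstroms.
COULOMB_V_ANG = 14.3996

#: Conversion factor from e·V to kcal/mol (Faraday constant / 4184).
EV_TO_KCAL = 23.0609

#: Coulomb constant for pairwise protein electrostatics, Å·kcal/(mol·e²).
C0 = 322.0

#: Pairwise electrostatics cutoff, Å.  Energies are exactly zero beyond it.
R_MAX = 5.5

#: Depth at which the aqueous phase defines the zero of the bilayer
#: potential, Å.
WATER_REFERENCE_Z = 40.0
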