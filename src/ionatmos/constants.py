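"""Physical constants and unit conventions.

All lengths are nm, concentrations mol/L, energies k_BT, charges in units of
the elementary charge e.  The electrostatic potential is reduced, phi = e*psi/k_BT.
"""

AVOGADRO = 6.02214076e23
"""Avogadro's number, 1/mol."""

VF_L_PER_NM3 = 1.0e-24
"""Volume conversion factor: litres per cubic nanometre."""

MOLAR_TO_PER_NM3 = AVOGADRO * VF_L_PER_NM3
"""N_A * V_f: converts a concentration in mol/L to a number density in nm^-3."""

BJERRUM_NM = 0.714
"""Bjerrum length of water at 300 K, nm."""

DEFAULT_DUPLEX_CHARGE = 64.0
"""Backbone charge magnitude of a 33-bp duplex: 2*(n_bp - 1) = 64 e."""
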