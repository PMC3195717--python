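"""Unit system and conversion constants.

Internal convention: lengths in Angstrom, time in fs, mass in amu,
energy in kcal/mol.  The integrator works in "internal" energy units of
amu*A^2/fs^2; a single constant converts to and from kcal/mol.
"""

from scipy import constants as _c

#: 1 kcal/mol expressed in amu*A^2/fs^2.
KCAL_MOL_TO_INTERNAL: float = _c.calorie * 1e3 / (_c.atomic_mass * _c.Avogadro * 1e10)

#: 1 amu*A^2/fs^2 expressed in kcal/mol.
INTERNAL_TO_KCAL_MOL: float = 1.0 / KCAL_MOL_TO_INTERNAL

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_MOL: float = _c.R / (_c.calorie * 1e3)

#: Boltzmann constant in internal units (amu*A^2/fs^2 per K).
KB_INTERNAL: float = KB_KCAL_MOL * KCAL_MOL_TO_INTERNAL
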