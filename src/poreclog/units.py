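"""Unit conventions and physical constants.

The package works in Å (length), ps (time) and elementary charges. Ionic
currents are reported in nA: a charge flux of 1 e/ps equals
1.602176634e-19 C / 1e-12 s = 1.602176634e-7 A = 160.2176634 nA.
"""

ELEMENTARY_CHARGE_C = 1.602176634e-19
"""Elementary charge in coulomb (2019 SI exact value)."""

E_PER_PS_TO_NA = ELEMENTARY_CHARGE_C / 1e-12 * 1e9
"""Conversion factor from e/ps to nA (= 160.2176634)."""

PS_PER_NS = 1000.0
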