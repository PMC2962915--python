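"""Concentration units.

Every concentration inside the package is stored in molar (M). The
published conventions of the field mix micromolar (modification reagent)
with millimolar (coenzymes), which makes the dimensionless ratios in the
rate laws easy to get silently wrong; converting once, at the interface,
removes that failure mode.

Use the constants multiplicatively::

    from shprotect.units import uM, mM
    params = InactivationParams(j=3.52e-3, k_dtnb=990 * uM)

and the ``to_*`` helpers when rendering molar quantities back into
interface units.
"""

#: one micromolar, in molar
uM: float = 1e-6
#: one millimolar, in molar
mM: float = 1e-3
#: one molar (identity; included for explicitness in tables of units)
M: float = 1.0


def to_uM(conc_molar: float) -> float:
    """Express a molar concentration in µM."""
    return conc_molar / uM


def to_mM(conc_molar: float) -> float:
    """Express a molar concentration in mM."""
    return conc_molar / mM
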