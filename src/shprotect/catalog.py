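"""Reference parameter catalog for clostridial glutamate dehydrogenase.

Published characterisation of the NAD⁺-dependent GDH of *Clostridium
symbiosum* (wild-type) and four engineered coenzyme-binding-site
variants — F238S, P262S, the double mutant F238S/P262S, and D263K —
modified at Cys-320 by Ellman's reagent (DTNB) at pH 7.0:

* per-variant covalent rate constant ``j`` and reagent dissociation
  constant ``K_DTNB``, with standard errors;
* per-variant dissociation constants of the binary complexes with
  NAD⁺, NADH and NADPH, determined by the protection method.

These numbers serve as ground truth for the synthetic-data generator
and as the worked example throughout the package; they are bundled
data, never recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import CoenzymeBinding, InactivationParams
from .units import mM, uM

__all__ = [
    "VariantRecord",
    "reference_catalog",
    "WILD_TYPE",
    "COENZYMES",
]

#: identifier of the unmutated enzyme, the reference for fold changes
WILD_TYPE = "wild-type"

#: coenzymes characterised for every variant
COENZYMES = ("NAD+", "NADH", "NADPH")


@dataclass(frozen=True)
class VariantRecord:
    """Catalog entry: baseline modification parameters plus ligand affinities."""

    variant: str
    params: InactivationParams
    se_j: float
    se_k_dtnb: float
    bindings: dict[str, CoenzymeBinding]
    se_kd: dict[str, float]


# (j s^-1, se_j, K_DTNB M, se, {coenzyme: (Kd M, se)})
_ROWS = {
    "wild-type": (3.52e-3, 0.14e-3, 990 * uM, 6.8 * uM,
                  {"NAD+": (0.335 * mM, 0.017 * mM),
                   "NADH": (0.024 * mM, 0.001 * mM),
                   "NADPH": (0.023 * mM, 0.001 * mM)}),
    "F238S": (7.95e-3, 0.22e-3, 1190 * uM, 17.5 * uM,
              {"NAD+": (6.62 * mM, 0.25 * mM),
               "NADH": (0.232 * mM, 0.056 * mM),
               "NADPH": (1.30 * mM, 0.056 * mM)}),
    "P262S": (3.45e-3, 0.17e-3, 758 * uM, 23.1 * uM,
              {"NAD+": (2.84 * mM, 0.22 * mM),
               "NADH": (0.052 * mM, 0.004 * mM),
               "NADPH": (0.375 * mM, 0.03 * mM)}),
    "F238S/P262S": (5.28e-3, 0.36e-3, 981 * uM, 13.4 * uM,
                    {"NAD+": (4.30 * mM, 0.38 * mM),
                     "NADH": (0.253 * mM, 0.021 * mM),
                     "NADPH": (0.526 * mM, 0.045 * mM)}),
    "D263K": (2.50e-3, 0.12e-3, 338 * uM, 14.5 * uM,
              {"NAD+": (2.02 * mM, 0.21 * mM),
               "NADH": (0.130 * mM, 0.012 * mM),
               "NADPH": (0.228 * mM, 0.021 * mM)}),
}


def reference_catalog() -> dict[str, VariantRecord]:
    """Build the full five-variant catalog as fresh, immutable records."""
    out: dict[str, VariantRecord] = {}
    for name, (j, se_j, kd_dtnb, se_kd_dtnb, coz) in _ROWS.items():
        out[name] = VariantRecord(
            variant=name,
            params=InactivationParams(j=j, k_dtnb=kd_dtnb),
            se_j=se_j,
            se_k_dtnb=se_kd_dtnb,
            bindings={c: CoenzymeBinding(coenzyme=c, kd=kd) for c, (kd, _) in coz.items()},
            se_kd={c: se for c, (_, se) in coz.items()},
        )
    return out
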