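"""Determine a ligand dissociation constant by the protection method.

Stage 1: DTNB saturation series (50-600 uM) gives the baseline (j,
K_DTNB) for the enzyme. Stage 2: protection series at 200 uM DTNB with
graded NAD+ gives Kd from the reciprocal protection line. Run here on
noiseless synthetic data generated from the wild-type reference values,
so recovery should be essentially exact.
"""

from shprotect import (
    ExperimentDesign,
    NoiseSpec,
    ProtectionSeries,
    SignalModel,
    fit_kd,
    fit_rate_activity,
    fit_saturation,
    generate_dtnb_series,
    generate_protection_series,
)
from shprotect.catalog import reference_catalog
from shprotect.units import to_mM, to_uM

rec = reference_catalog()["wild-type"]
design = ExperimentDesign()
sig = SignalModel(mode="activity")
noise = NoiseSpec()  # noiseless

courses = generate_dtnb_series(rec.params, design, sig, noise, variant="wild-type")
sat = fit_saturation([fit_rate_activity(tc) for tc in courses])
print(f"stage 1 (saturation): j = {sat.j:.4g} 1/s, "
      f"K_DTNB = {to_uM(sat.k_dtnb):.1f} uM")

prot = generate_protection_series(rec.params, rec.bindings["NAD+"], design, sig, noise,
                                  variant="wild-type")
series = ProtectionSeries.from_rates([fit_rate_activity(tc) for tc in prot])
res = fit_kd(series, sat)
print(f"stage 2 (protection): Kd(NAD+) = {to_mM(res.kd):.4g} mM, "
      f"intercept consistency = {res.consistency_ratio:.6f}")
print("Kd comes from the protection-line slope; a consistency ratio of 1 means the")
print("line's intercept reproduces the zero-ligand rate predicted by stage 1.")
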