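"""Full study pipeline: simulate, fit, and compare five enzyme variants.

Simulates the complete study (one saturation series plus three
coenzyme protection series per variant) from the bundled reference
catalog, runs both fitting stages, and prints the cross-variant
comparison: Kd per coenzyme, the NADPH/NADH discrimination ratio, and
fold changes versus the wild-type enzyme.
"""

import tempfile

from shprotect import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as out:
    cfg = RunConfig(mode="full", out_dir=out, seed=1)
    report = run_pipeline(cfg)
    print("baseline parameters per variant:")
    print(report.saturation[["variant", "j_s", "K_DTNB_uM"]].to_string(index=False))
    print()
    print("comparison table (Kd in mM; folds vs wild-type):")
    cols = [c for c in report.comparison.columns if not c.startswith("se_")]
    print(report.comparison[cols].to_string())

print()
print("A discrimination ratio Kd(NADPH)/Kd(NADH) > 1 means the variant binds the")
print("phosphorylated reduced coenzyme more weakly than NADH; rising folds show")
print("every mutation weakened binding of all three coenzymes.")
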