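"""Select coffee-intake instruments the way the packaged analyses do.

Starts from the 11 East Asian candidate variants, shows their
single-variant F-statistics, applies the documented pleiotropy-screen
preset (which drops GCKR, ALDH2, APOE5, MIR2113 while protecting the AHR
variant), and prints what survives alongside the published robust set.
"""

from mrkit import (PLEIOTROPY_PRESETS, SelectionConfig, f_statistic,
                   load_fixture, select_instruments)

candidates = load_fixture("ea_coffee_exposure_11")
print(f"{len(candidates)} candidate instruments for coffee intake")
for r in candidates:
    print(f"  {r.variant_id:<11} ({r.gene:<12}) beta={r.beta:+.3f}  "
          f"F={f_statistic(r):7.1f}  p={r.pvalue:.2e}")

preset = PLEIOTROPY_PRESETS["ea_coffee"]
config = SelectionConfig(manual_exclusions={v: "pleiotropy screen"
                                            for v in preset["manual_exclusions"]},
                         protected_variants=preset["protected_variants"])
kept, log = select_instruments(candidates, config)
print(f"\nkept after screening: {sorted(r.variant_id for r in kept)}")
for rec in log:
    print(f"  excluded {rec.variant_id}: {rec.stage} ({rec.reason})")

robust = sorted(r.variant_id for r in load_fixture("ea_coffee_exposure_robust7"))
print(f"\npublished robust set (after heterogeneity pruning): {robust}")
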