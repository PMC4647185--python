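"""Multiple imputation of missing MAP values with Rubin's-rules pooling.

Routine antenatal records are incomplete; chained-equations imputation
(posterior-draw conditional models, outcomes included as predictors)
restores full tables, normative values are recomputed passively in each,
and coefficient estimates are pooled across imputations.  Here 20% of the
28-week MAP values are removed completely at random and the pooled
current-MAP coefficient is compared with its complete-data value.
"""

import numpy as np

import bpscreen as b

cfg = b.alspac_like_config(n=4000, seed=13)
cohort = b.generate_cohort(cfg)
derived = b.derive_table(cohort)

imp_full = b.complete_data_set(derived)
terms = ["bmi", "parity_1", "parity_2plus", "essential_htn",
         "initial_map", "map_28"]
full = b.fit_logistic(imp_full, "pe", terms, gestation=28, model_id=2)
print(f"complete-data map_28 coefficient: {full.coef['map_28']:.4f} "
      f"(SE {np.sqrt(full.coef_var['map_28']):.4f})")

rng = np.random.default_rng(5)
dmiss = derived.copy()
drop = rng.random(len(dmiss)) < 0.2
dmiss.loc[drop, "map_28"] = np.nan
print(f"removed {drop.sum()} of {len(dmiss)} map_28 values (MCAR)")

imp = b.impute_chained(dmiss, m=10, n_cycles=5, seed=9)
pooled = b.fit_logistic(imp, "pe", terms, gestation=28, model_id=2)
se = np.sqrt(pooled.coef_var["map_28"])
shift = (pooled.coef["map_28"] - full.coef["map_28"]) / se
print(f"pooled map_28 coefficient (m=10): {pooled.coef['map_28']:.4f} "
      f"(SE {se:.4f}; shift {shift:+.2f} SE)")

pe = b.rubin_combine([0.9, 1.1], [0.04, 0.04])
print(f"\nRubin's rules, hand case (0.9, 1.1 with variances 0.04):")
print(f"  estimate {pe.estimate:.2f}, total variance {pe.total_var:.3f} "
      f"(within 0.04 + 1.5 x between 0.02)")
print("\nThe pooled coefficient stays within sampling error of the")
print("complete-data fit, and the pooled variance reflects both the")
print("within- and between-imputation uncertainty.")
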