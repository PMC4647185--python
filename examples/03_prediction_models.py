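"""Build the gestation-indexed prediction models and compare their AUCs.

Stage 2: logistic models for pre-eclampsia on women not yet delivered at
each index gestation.  Model 1 uses early-pregnancy characteristics
(backward-selected, pooled Wald P<0.2) plus the booking MAP; model 2 adds
the current MAP; model 3 adds the deviation from the woman's conditional
normative value; model 4 adds both.  The printed table shows the central
finding: current blood pressure adds discrimination, increasingly so with
gestation, while the normogram deviation performs like the raw value.
"""

import bpscreen as b

cfg = b.alspac_like_config(n=6000, seed=3)
cohort = b.generate_cohort(cfg)
derived = b.derive_table(cohort)
fits = b.fit_normograms(cohort, derived, subsample=1500, seed=1)
imp = b.passive_normative(b.complete_data_set(derived), fits)

registry = b.build_all_models(imp, outcomes=("pe",))
m1 = registry[("pe", 1, "booking")]
print("model 1 terms:", ", ".join(m1.terms))

print(f"\n{'week':>6} {'n':>6} {'model1':>8} {'model2':>8} "
      f"{'model3':>8} {'model4':>8}")
for g in (20, 25, 28, 31, 34, 36):
    row = [f"{g:>6}", f"{registry[('pe', 1, g)].n_population:>6}"]
    for mid in (1, 2, 3, 4):
        a, _ = b.pooled_auc(registry[("pe", mid, g)], imp)
        row.append(f"{a:>8.3f}")
    print(" ".join(row))

tab = imp.completed_tables[0]
sub = tab[tab.ga_delivery > 36]
import numpy as np
s1 = registry[("pe", 1, 36)].predict_risk(sub, on_missing="nan")
s2 = registry[("pe", 2, 36)].predict_risk(sub, on_missing="nan")
ok = np.isfinite(s1) & np.isfinite(s2)
p = b.compare_auc_bootstrap(s1[ok], s2[ok], sub.pe.to_numpy()[ok],
                            B=300, seed=5)
print(f"\nbootstrap Wald p-value, model 2 vs 1 at 36 weeks: {p:.2g}")
print("Model 2's AUC rises steadily with gestation while model 1 is flat;")
print("models 3 and 4 track model 2 (the deviation carries the same")
print("information as the raw current value once booking MAP is included).")
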