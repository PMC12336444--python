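"""Single-marker and combined-model diagnostic evaluation.

Evaluates the reconstructed 35-patient reference cohort: ROC analysis with
Youden-index cutoff selection for each marker, then combined scoring models
(binarize each marker at its cutoff, sum, ROC on the total score).
"""

from ctcdx import combined_model, compare_models, evaluate_marker, reference_cohort

cohort, sidecar = reference_cohort()

print("single markers (cutoff = Youden-optimal observed value):")
singles = []
for marker in ("msln_ctc_count", "ctc_count", "ca125_u_ml", "he4_pmol_l"):
    rep = evaluate_marker(cohort, marker)
    singles.append(rep)
    c = rep.cutoff
    print(f"  {marker:16s} n={rep.n_cases}/{rep.n_controls}  "
          f"cutoff>={c.cutoff_observed:g}  sens={100*c.sensitivity:.2f}%  "
          f"spec={100*c.specificity:.2f}%  AUC={rep.curve.auc:.3f}")

print("\ncombined scoring models (score cutoff in points):")
models = []
for markers in [("msln_ctc_count", "ca125_u_ml"), ("msln_ctc_count", "he4_pmol_l"),
                ("ctc_count", "ca125_u_ml"), ("ctc_count", "he4_pmol_l"),
                ("msln_ctc_count", "ca125_u_ml", "he4_pmol_l"),
                ("ctc_count", "ca125_u_ml", "he4_pmol_l")]:
    m = combined_model(cohort, markers)
    models.append(m)
    c = m.cutoff
    print(f"  {m.name:45s} cutoff>{c.threshold:g}  sens={100*c.sensitivity:.2f}%  "
          f"spec={100*c.specificity:.2f}%")

table = compare_models(singles + models)
best = table[table["both_above_90"]]
print("\nmodels with sensitivity AND specificity > 90%:")
print(best[["model", "sensitivity_pct", "specificity_pct"]].to_string(index=False))
# A score cutoff of 0.5 points means "positive on at least one marker";
# 1.5 points means "positive on at least two".
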