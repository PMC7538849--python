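"""Compare clinical vs imaging predictor pools for 5-year survival.

Wires outcomes to tumor composition (clinical covariates stay
non-informative), runs stratified 10-fold cross-validation with the
logistic family, and prints the AUC of each pool plus the integrated
discrimination improvement.
"""

import lucency as lc

cfg = lc.SimConfig(n_subjects=250, rdc_beta=5.0, baseline_hazard=0.04,
                   censoring_rate=0.0)
bundle = lc.generate_cohort(cfg, seed=21)
ibm = lc.ibm_table(bundle.volumes)
cbm, _ = lc.build_feature_table(bundle.clinical)
cohort = (
    cbm.merge(ibm, on="subject_id")
    .merge(bundle.outcomes, on="subject_id")
    .dropna(subset=["five_year_label"])
)

comparison = lc.compare_feature_sets(cohort, families=("lr",), k=10, seed=21)
print(comparison.metrics.to_string(index=False))
print()
print(comparison.idi.to_string(index=False))
print("\nOutcomes are driven by composition only, so the imaging pool (IBM)")
print("discriminates while the clinical pool (CBM) stays near AUC 0.5; the")
print("positive IDI quantifies that gain in discrimination slope.")
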