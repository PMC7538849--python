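"""Encode clinical covariates the way the classifiers consume them.

Shows the nominal {0,1} mapping and the stage-proportion encoding on a
cohort where 16 of 68 subjects are stage T1.
"""

import lucency as lc
from lucency.simulate import SimConfig, generate_clinical

print("nominal encodings:")
print("  Male   ->", lc.encode_binary_nominal("Male", ("Male", "Female")))
print("  Female ->", lc.encode_binary_nominal("Female", ("Male", "Female")))

column = [1] * 16 + [2] * 30 + [3] * 15 + [4] * 7
mapping = lc.stage_proportion_encoding(column)
print("\nstage-proportion encoding (16 of 68 at T1):")
for stage, value in sorted(mapping.items()):
    print(f"  T{stage} -> {value:.3f}")
print("a T1 subject is encoded as 16/68 = %.3f" % mapping[1])

clinical = generate_clinical(SimConfig(n_subjects=8), seed=0)
encoded, excluded = lc.build_feature_table(clinical)
print("\nencoded synthetic cohort (first rows):")
print(encoded.head().to_string(index=False))
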