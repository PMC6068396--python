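"""Run a restricted model grid and compare factor levels with Tukey's test.

Executes preprocessing x SVM cells with replicated cross-validation, then
summarizes mean recall per Savitzky-Golay window size and tests the levels
with Tukey's range test at p = 0.05 (levels sharing a letter are not
significantly different).
"""

from vinehsi import (ModelConfig, PreprocessConfig, factor_summary,
                     make_sample_table, run_grid, tukey_factor)

table = make_sample_table(n_varieties=5, n_days=1, samples_per_variety_day=20,
                          n_bands=60, separation=0.15, noise_sd=0.05, seed=6)
preprocess_configs = [PreprocessConfig(scatter=False, deriv_order=1, sg_window=w)
                      for w in (5, 9, 15)]
model_configs = [ModelConfig("svm", svm_C=c, svm_kernel="linear")
                 for c in (0.1, 1.0, 10.0)]
rows = run_grid(table, seeds=[1, 2, 3], preprocess_configs=preprocess_configs,
                model_configs=model_configs)
print(f"grid rows: {len(rows)} (3 windows x 3 C values x 3 replicates)")

print("\nmean recall per window size (descending):")
print(factor_summary(rows, "sg_window", "recall").to_string(index=False))

result = tukey_factor(rows, "sg_window", "recall", alpha=0.05)
print("\nTukey HSD on window size (shared letter = not significantly different):")
for level, mean, letters in zip(result.levels, result.means, result.groups):
    print(f"  window {level}: mean recall {mean:.4f}  [{letters}]")

result_c = tukey_factor(rows, "svm_C", "recall", alpha=0.05)
print("\nTukey HSD on the SVM penalty C:")
for level, mean, letters in zip(result_c.levels, result_c.means, result_c.groups):
    print(f"  C={level:g}: mean recall {mean:.4f}  [{letters}]")
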