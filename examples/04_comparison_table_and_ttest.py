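"""Build the per-group comparison table and its pooled two-sample t-test.

Given final-hold-out accuracies of the three arms across four phenotypes,
the table reports each arm, the improvements over the no-transfer baseline,
and a Student pooled-variance t-test between the no-transfer and
deep-transfer accuracy vectors.
"""

from genotransfer import build_comparison_table

fd_accuracies = {
    "5_1": {"no_transfer": 56, "snp_transfer": 48, "deep_transfer": 58},
    "5_2": {"no_transfer": 52, "snp_transfer": 54, "deep_transfer": 58},
    "5_3": {"no_transfer": 44, "snp_transfer": 44, "deep_transfer": 64},
    "5_4": {"no_transfer": 42, "snp_transfer": 38, "deep_transfer": 56},
}

table = build_comparison_table(fd_accuracies)
print(table)
# Improvements may be negative (negative transfer); the t-test asks whether
# the deep-transfer accuracies beat the baselines beyond chance across the
# four phenotypes.
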