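"""Apply the QC filters and compute percent methylation with exact intervals.

Shows the four-step filter cascade (genotype/SNP sites, low-coverage fish,
site presence, confidence-interval width) and the per-cell Clopper-Pearson
bounds that drive the width filter.
"""

from finclock import (
    SyntheticConfig, apply_qc, clopper_pearson_interval, global_methylation_summary,
    percent_methylation, simulate_cohort, simulate_untreated_substitutions,
)

config = SyntheticConfig(seed=1)
matrix, fish, truths = simulate_cohort(config)
substitutions = simulate_untreated_substitutions(config, truths)

# min_sites is the per-individual coverage threshold; the published value
# (400,000 observed CpG sites) is for sequencing scale, so scale it down here
filtered, accounting = apply_qc(matrix, substitutions, min_sites=50)
for key, value in accounting.items():
    print(f"{key:30s} {value}")

pm = percent_methylation(filtered)
mean, sd = global_methylation_summary(pm)
print(f"\nglobal methylation across retained sites: {100 * mean:.2f}% (+-{100 * sd:.2f}%)")

low, high = clopper_pearson_interval(8, 16)
print(f"a cell with 8/16 methylated reads: p = 0.50, 95% CI ({low:.3f}, {high:.3f}), "
      f"width {high - low:.3f} -> passes the < 0.85 width filter")
low2, high2 = clopper_pearson_interval(1, 2)
print(f"a cell with 1/2 reads:            p = 0.50, 95% CI ({low2:.3f}, {high2:.3f}), "
      f"width {high2 - low2:.3f} -> too wide, the site needs deeper coverage")
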