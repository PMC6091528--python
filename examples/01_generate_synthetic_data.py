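"""Generate a synthetic dose-response feature table with planted biomarkers.

The generator emulates an XCMS-style aligned GC-MS export: 5 exposure levels
(0-1250 ug/L), 5 tubes x 4 individuals per level, log-normal abundances, and
a small set of bins that respond to dose.  The ground truth records which
bins were planted so downstream recovery can be scored.
"""

import metabomark as mm

config = mm.SyntheticConfig(n_bins=1000, n_planted=15, effect_size=2.0,
                            noise_sigma=0.5, species_label="demo", seed=42)
table, truth = mm.generate_feature_table(config)

print(f"table: {table.n_samples} samples x {table.n_bins} bins")
print("samples per concentration:")
print(table.sample_meta.groupby("concentration_ug_per_L").size().to_string())
print(f"planted bins ({len(truth.planted_bins)}), first five with directions:")
for b in truth.planted_bins[:5]:
    sign = "+" if truth.per_bin_direction[b] > 0 else "-"
    print(f"  {b}  {sign}")
# Each planted bin shifts by up to effect_size log2 units at the top dose;
# everything else is exchangeable noise, so any bin ranked above a planted
# one downstream is a false discovery.
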