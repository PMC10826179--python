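"""Generate a synthetic FFPE miRNA qPCR cohort and inspect its structure.

The generator emulates an 88-subject study (19 reactive lymph nodes,
49 nTFHL, 20 nPTCL) on a 376-miRNA panel: spike-in control rows carry
per-sample technical offsets, ~130 miRNAs fall below the detection-rate
filter, and planted class effects (here 22 shared-lymphoma shifts)
define the ground truth that downstream analyses should recover.
"""

import lymphomir as lm

effects = lm.sample_effects(22, shift_range=(1.5, 2.0), seed=1)
config = lm.CohortConfig(effects=effects, seed=1)
matrix, annotation, truth = lm.simulate_cohort(config)

print(f"Ct matrix: {matrix.n_mirnas} rows x {matrix.n_samples} samples")
print(f"spike-in rows: {matrix.spike_in_ids()}")
print(f"class counts: {annotation.class_counts()}")
frac = matrix.detection_fraction()[~matrix.is_spike_in]
print(f"miRNAs detected in <10% of samples: {(frac < 0.10).sum()}")
print(f"planted low-detection miRNAs: {len(truth.low_detection_ids)}")
print("first planted effect log2FCs (grouped comparison):")
print(truth.log2fc[truth.log2fc['grouped'] != 0].head(3))
# A positive log2FC means the miRNA is upregulated in lymphoma relative
# to reactive lymph nodes (planted Ct shift with the opposite sign).
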