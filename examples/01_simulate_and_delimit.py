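"""Generate a synthetic barcode study and delimit putative species.

Builds 6 species x 4 individuals of 650 bp COI-like sequences with a clear
barcode gap (1% within species, 10% between the closest species), then runs
the two distance-based delimitation methods and compares their group counts
with the known truth.
"""

import barconcord as bc

ds = bc.generate(bc.SyntheticConfig(
    n_species=6, samples_per_species=4, seed=42,
))
dm = bc.p_distance_matrix(ds.sequences)
report = bc.calibration_report(ds.sequences, ds.truth.assignment)
print(f"max within-species p-distance: {report['max_intra']:.4f}")
print(f"min between-species p-distance: {report['min_inter']:.4f}")
print(f"barcode-gap ratio: {report['gap_ratio']:.1f}")

abgd = bc.abgd_partition(dm, prior=0.02)
linkage = bc.single_linkage_partition(dm, threshold=0.022)
print(f"true species: {ds.truth.n_groups()}")
print(f"barcode-gap partition groups: {abgd.n_groups()}")
print(f"single-linkage (2.2%) groups: {linkage.n_groups()}")
# Both methods should report 6 putative species: with a gap ratio well
# above 1 every within-species pair links below the threshold and no
# between-species pair does.
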