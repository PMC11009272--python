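"""Oxygen penetration depth and depth-averaged NOB community composition.

Builds a linear O2 profile, infers the OPD by interpolation at a 1 uM
threshold, splits samples into redox zones, and depth-averages the NOB
lineage fractions over the oxic zone with trapezoidal integration.
"""

import nitribalance as nb

profile = nb.make_o2_profile([0, 9, 18, 30], opd_cm=18, o2_surface_uM=10, core_id="demo")
estimate = nb.infer_opd(profile, threshold_uM=1.0)
print(f"O2 {profile.o2_uM.tolist()} uM at {profile.depth_cm.tolist()} cm")
print(f"inferred OPD at 1 uM: {estimate.opd_cm:.1f} cm (bounded={estimate.bounded})")
print()

dataset = nb.generate_dataset(nb.SyntheticParams(seed=7))
guild_map = nb.assign_guilds(
    dataset.taxonomy, verified_candidate_otus=dataset.verified_candidate_otus
)
absolute = nb.absolute_abundances(
    nb.relative_abundances(dataset.otu_table, guild_map), dataset.samples
)
opd = {core: nb.infer_opd(p).opd_cm for core, p in dataset.geochem.items()}
zones = nb.split_redox_zones(dataset.samples, opd)
composition = nb.nob_composition(absolute, dataset.samples, zones)

print("depth-averaged NOB composition in the oxic zone (first three cores):")
print(composition.depth_averaged.head(3).round(3))
print()
print("The candidate lineage carries about two thirds of the NOB cells at every")
print("depth, matching the fraction planted by the generator (0.65).")
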