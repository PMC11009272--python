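"""Full pipeline on a synthetic survey: recover a planted AOA:NOB ratio and
show how reattributing the candidate lineage to the NOB guild collapses the
apparent AOA excess.

The generator plants a true oxic-zone AOA:NOB cell ratio of 10 with the
candidate lineage carrying 65% of NOB cells, then observes it through
multinomial amplicon counts (30k reads/sample) and lognormal qPCR noise.
"""

import nitribalance as nb

dataset = nb.generate_dataset(nb.SyntheticParams(seed=7))
guild_map = nb.assign_guilds(
    dataset.taxonomy, verified_candidate_otus=dataset.verified_candidate_otus
)
rel = nb.relative_abundances(dataset.otu_table, guild_map)
absolute = nb.absolute_abundances(rel, dataset.samples)
opd = {core: nb.infer_opd(profile).opd_cm for core, profile in dataset.geochem.items()}
zones = nb.split_redox_zones(dataset.samples, opd)

result = nb.reattribution_analysis(
    absolute, zones, nb.theoretical_band(), n_boot=10000, seed=1
)

for name, arm in (
    ("canonical NOB only ", result.without_candidate),
    ("incl. candidate NOB", result.with_candidate),
):
    s = arm.summary
    print(
        f"{name}: median AOA:NOB = {s.median:5.1f}  "
        f"99% CI [{s.ci_low:.1f}, {s.ci_high:.1f}]  "
        f"above band: {s.n_above_band}/{s.n}  "
        f"OLS slope {arm.fit.slope:.1f} (r2 {arm.fit.r_squared:.2f})"
    )
print()
print(f"median inflation without the candidate: {result.median_ratio:.2f}")
print(f"expected from the planted candidate share: {1 / (1 - 0.65):.2f}")
print()
print("With only canonical families counted, every oxic sample sits far above")
print("the theoretical band; adding the candidate lineage returns the medians")
print("to the planted ratio of 10, inside the band.")
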