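"""Screen amplicon read sets against a query 16S sequence.

A read matches when it is longer than 200 bp and more than 95% identical to
the query (either orientation). Samples with fewer than 10 matching reads are
discarded, and only samples where matches exceed 0.1% of all reads are
retained for mapping.
"""

import numpy as np

import nitribalance as nb

rng = np.random.default_rng(3)
query = "".join(rng.choice(list("ACGT"), size=1565))


def reads_for(n_matching, n_junk):
    matching = [("hit", query[100 + i : 401 + i]) for i in range(n_matching)]
    junk = [("junk", "".join(rng.choice(list("ACGT"), size=50))) for _ in range(n_junk)]
    return matching + junk


samples = {
    "rich_site": reads_for(40, 4000),     # 40/4040 = 0.99% -> retained
    "sparse_site": reads_for(6, 4000),    # 6 hits -> discarded_low_hits
    "dilute_site": reads_for(12, 20000),  # 12/20012 = 0.06% -> below_abundance
}

results = [
    nb.screen_sample(reads, query, sample_id=name) for name, reads in samples.items()
]
for r in results:
    print(f"{r.sample_id:12s} {r.n_matching_reads:3d}/{r.n_reads_total:5d} matching "
          f"({r.relative_abundance_percent:.2f}%) -> {r.status}")

retained = nb.retain_for_mapping(results)
print()
print(f"retained for mapping: {[r.sample_id for r in retained]}")
print("Only sites passing both the hit-count and abundance filters would be")
print("plotted on an occurrence map.")
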