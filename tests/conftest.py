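import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nitribalance as nb

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset() -> nb.SyntheticDataset:
    """The standard study conditions: 10 cores, 100 oxic + 20 anoxic samples,
    r_true=10, f_candidate=0.65, qPCR sigma 0.3, 30k reads per sample."""
    return nb.generate_dataset(nb.SyntheticParams(seed=7))


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    """Guild map, absolute abundances and redox zones for the default dataset."""
    ds = default_dataset
    guild_map = nb.assign_guilds(
        ds.taxonomy, verified_candidate_otus=ds.verified_candidate_otus
    )
    rel = nb.relative_abundances(ds.otu_table, guild_map)
    absolute = nb.absolute_abundances(rel, ds.samples)
    opd = {core: nb.infer_opd(profile).opd_cm for core, profile in ds.geochem.items()}
    zones = nb.split_redox_zones(ds.samples, opd)
    return ds, guild_map, rel, absolute, zones


def noise_free_dataset(r_true: float, f_candidate: float, seed: int = 11) -> nb.SyntheticDataset:
    """Noise-free survey whose expected per-OTU counts are exact integers:
    background off, qPCR noise off, deterministic expected counts, and
    r_true/read_depth chosen so every oxic-zone relative abundance times the
    read depth is integral."""
    params = nb.SyntheticParams(
        n_cores=2,
        depths_cm=(2, 6, 10, 14, 18, 30),
        opd_cm=20.0,
        r_true=r_true,
        f_candidate=f_candidate,
        background_otus=0,
        qpcr_sigma=0.0,
        read_depth=32000,
        count_model="expected",
        seed=seed,
    )
    return nb.generate_dataset(params)


def run_balance(dataset: nb.SyntheticDataset, n_boot: int = 500, seed: int = 1):
    """Full analysis path: counts -> guilds -> abundances -> zones -> reattribution."""
    guild_map = nb.assign_guilds(
        dataset.taxonomy, verified_candidate_otus=dataset.verified_candidate_otus
    )
    rel = nb.relative_abundances(dataset.otu_table, guild_map)
    absolute = nb.absolute_abundances(rel, dataset.samples)
    opd = {c: nb.infer_opd(p).opd_cm for c, p in dataset.geochem.items()}
    zones = nb.split_redox_zones(dataset.samples, opd)
    return nb.reattribution_analysis(
        absolute, zones, nb.theoretical_band(), n_boot=n_boot, seed=seed
    )
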