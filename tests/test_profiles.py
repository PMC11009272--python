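import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import nitribalance as nb
from nitribalance.errors import ParameterError
from nitribalance.guilds import GUILD_CANDIDATE, NOB_LINEAGES

from _oracles import piecewise_linear_average
from conftest import noise_free_dataset


def _one_guild_table(counts, guild="X"):
    otus = [f"OTU_{i}" for i in range(len(counts))]
    table = nb.OtuTable(
        pd.DataFrame([counts], index=["S1"], columns=otus, dtype=np.int64)
    )
    gm = nb.GuildMap({o: guild for o in otus}, {o: "" for o in otus})
    return table, gm


class TestRelativeAbundances:
    def test_whole_sample_one_guild(self):
        table, gm = _one_guild_table([5, 5, 10])
        rel = nb.relative_abundances(table, gm)
        assert rel.values.loc["S1", "X"] == pytest.approx(1.0)

    def test_partial_guild_fraction(self):
        table, _ = _one_guild_table([5, 5, 10])
        gm = nb.GuildMap(
            {"OTU_0": "other", "OTU_1": "other", "OTU_2": "X"}, {}
        )
        rel = nb.relative_abundances(table, gm)
        assert rel.values.loc["S1", "X"] == pytest.approx(0.5)

    def test_all_zero_sample_rejected(self):
        table, gm = _one_guild_table([0, 0, 0])
        with pytest.raises(ParameterError, match="S1"):
            nb.relative_abundances(table, gm)

    def test_uncovered_otu_rejected(self):
        table, _ = _one_guild_table([1, 2, 3])
        gm = nb.GuildMap({"OTU_0": "X"}, {})
        with pytest.raises(ParameterError, match="OTU_1"):
            nb.relative_abundances(table, gm)

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=1000), min_size=4, max_size=4)
        .filter(lambda c: sum(c) > 0),
        seed=st.integers(min_value=0, max_value=100),
    )
    def test_guild_fractions_sum_to_one(self, counts, seed):
        rng = np.random.default_rng(seed)
        otus = [f"OTU_{i}" for i in range(4)]
        table = nb.OtuTable(
            pd.DataFrame([counts], index=["S1"], columns=otus, dtype=np.int64)
        )
        labels = {o: rng.choice(["A", "B", "other"]) for o in otus}
        rel = nb.relative_abundances(table, nb.GuildMap(labels, {}))
        assert rel.values.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-12)


class TestAbsoluteAbundances:
    def _samples(self, arch=4e7, bac=6e7):
        return nb.SampleTable(
            pd.DataFrame(
                dict(sample_id=["S1"], core_id=["C1"], depth_cm=[5.0],
                     qpcr_arch=[arch], qpcr_bac=[bac])
            )
        )

    def test_product_of_total_and_relative(self):
        rel = nb.AbundanceMatrix(pd.DataFrame({"X": [0.25]}, index=["S1"]), "relative")
        absolute = nb.absolute_abundances(rel, self._samples())
        assert absolute.values.loc["S1", "X"] == pytest.approx(2.5e7)

    def test_zero_relative_stays_zero_and_scaling_is_linear(self):
        rel = nb.AbundanceMatrix(
            pd.DataFrame({"X": [0.0], "Y": [0.4]}, index=["S1"]), "relative"
        )
        ab1 = nb.absolute_abundances(rel, self._samples())
        ab2 = nb.absolute_abundances(rel, self._samples(arch=8e7, bac=1.2e8))
        assert ab1.values.loc["S1", "X"] == 0.0
        np.testing.assert_allclose(ab2.values, 2 * ab1.values)

    def test_missing_qpcr_rejected(self):
        rel = nb.AbundanceMatrix(pd.DataFrame({"X": [0.25]}, index=["S2"]), "relative")
        with pytest.raises(ParameterError, match="S2"):
            nb.absolute_abundances(rel, self._samples())


class TestOpdAndZones:
    def test_interpolated_crossing(self):
        profile = nb.GeochemProfile("C1", [0, 9, 18, 30], o2_uM=[10, 5, 0, 0])
        assert nb.infer_opd(profile, 1.0).opd_cm == pytest.approx(16.2)

    def test_never_crossing_flagged_unbounded(self):
        profile = nb.GeochemProfile("C1", [0, 10, 20], o2_uM=[100, 90, 80])
        estimate = nb.infer_opd(profile, 1.0)
        assert estimate.opd_cm == 20.0
        assert not estimate.bounded

    def test_threshold_zero_boundary(self):
        profile = nb.GeochemProfile("C1", [0, 9, 18, 30], o2_uM=[10, 5, 0, 0])
        assert nb.infer_opd(profile, 0.0).opd_cm == pytest.approx(18.0)

    def test_missing_o2_instructs_user(self):
        profile = nb.GeochemProfile("C1", [0, 10], no3_uM=[5, 5])
        with pytest.raises(ParameterError, match="supply the OPD"):
            nb.infer_opd(profile)

    def test_zone_labels_and_closed_boundary(self):
        samples = nb.SampleTable(
            pd.DataFrame(
                dict(sample_id=["a", "b", "c"], core_id=["C1"] * 3,
                     depth_cm=[5.0, 16.2, 250.0], qpcr_arch=[1e7] * 3,
                     qpcr_bac=[1e7] * 3)
            )
        )
        zones = nb.split_redox_zones(samples, {"C1": 16.2})
        labels = dict(zip(zones.data["sample_id"], zones.data["zone"]))
        assert labels == {"a": "oxic", "b": "oxic", "c": "anoxic"}
        # partition: every sample labeled exactly once
        assert sorted(zones.sample_ids("oxic") + zones.sample_ids("anoxic")) == ["a", "b", "c"]

    def test_core_without_opd_rejected(self):
        samples = nb.SampleTable(
            pd.DataFrame(
                dict(sample_id=["a"], core_id=["C9"], depth_cm=[5.0],
                     qpcr_arch=[1e7], qpcr_bac=[1e7])
            )
        )
        with pytest.raises(ParameterError, match="C9"):
            nb.split_redox_zones(samples, {"C1": 10.0})


class TestDepthAveraging:
    def test_linear_profile(self):
        assert nb.depth_averaged_abundance([0, 1], [0, 100]) == pytest.approx(0.5)

    def test_constant_profile_invariance(self):
        assert nb.depth_averaged_abundance([3.7] * 4, [0, 7, 20, 31]) == pytest.approx(3.7)

    def test_uneven_grid_hand_value(self):
        # ((1+2)/2*10 + (2+4)/2*30) / 40 = 105/40 = 2.625
        assert nb.depth_averaged_abundance([1, 2, 4], [0, 10, 40]) == pytest.approx(2.625)

    def test_single_sample_needs_explicit_flag(self):
        with pytest.raises(ParameterError, match="allow_single"):
            nb.depth_averaged_abundance([1.0], [5.0])
        assert nb.depth_averaged_abundance([1.0], [5.0], allow_single=True) == 1.0

    @given(
        seed=st.integers(min_value=0, max_value=10**6),
        n=st.integers(min_value=2, max_value=12),
    )
    def test_matches_analytic_piecewise_linear_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        depths = np.sort(rng.uniform(0, 100, size=n))
        depths += np.arange(n) * 1e-3  # enforce strict increase
        values = rng.uniform(0, 50, size=n)
        mine = nb.depth_averaged_abundance(values, depths)
        oracle = piecewise_linear_average(depths, values)
        assert abs(mine - oracle) < 1e-10


class TestNobComposition:
    def test_simple_fractions(self):
        values = pd.DataFrame(
            {NOB_LINEAGES[0]: [2.0], NOB_LINEAGES[1]: [1.0], NOB_LINEAGES[2]: [1.0]},
            index=["S1"],
        )
        samples = nb.SampleTable(
            pd.DataFrame(dict(sample_id=["S1"], core_id=["C1"], depth_cm=[5.0],
                              qpcr_arch=[1e7], qpcr_bac=[1e7]))
        )
        comp = nb.nob_composition(nb.AbundanceMatrix(values, "absolute"), samples)
        np.testing.assert_allclose(comp.per_sample.loc["S1"], [0.5, 0.25, 0.25])

    def test_zero_nob_sample_excluded_with_warning(self):
        values = pd.DataFrame(
            {lin: [1.0, 0.0] for lin in NOB_LINEAGES}, index=["S1", "S2"]
        )
        samples = nb.SampleTable(
            pd.DataFrame(dict(sample_id=["S1", "S2"], core_id=["C1"] * 2,
                              depth_cm=[5.0, 10.0], qpcr_arch=[1e7] * 2,
                              qpcr_bac=[1e7] * 2))
        )
        with pytest.warns(UserWarning, match="zero total NOB"):
            comp = nb.nob_composition(nb.AbundanceMatrix(values, "absolute"), samples)
        assert comp.excluded_samples == ["S2"]
        assert list(comp.per_sample.index) == ["S1"]

    def test_candidate_share_passes_through_pipeline(self):
        # zero noise, f_candidate = 0.65: candidate fraction 0.65 at every oxic depth
        ds = noise_free_dataset(r_true=4.0, f_candidate=0.65)
        gm = nb.assign_guilds(ds.taxonomy, verified_candidate_otus=ds.verified_candidate_otus)
        absolute = nb.absolute_abundances(nb.relative_abundances(ds.otu_table, gm), ds.samples)
        zones = nb.split_redox_zones(
            ds.samples, {c: nb.infer_opd(p).opd_cm for c, p in ds.geochem.items()}
        )
        comp = nb.nob_composition(absolute, ds.samples, zones)
        np.testing.assert_allclose(comp.per_sample[GUILD_CANDIDATE], 0.65, rtol=1e-9)
        np.testing.assert_allclose(comp.depth_averaged[GUILD_CANDIDATE], 0.65, rtol=1e-9)
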