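import numpy as np
import pandas as pd
import pytest

from limnoch4 import community as comm
from limnoch4.community import OtuTable, QpcrStandard
from limnoch4.config import SyntheticConfig
from limnoch4.synthetic import generate_otu_table, generate_qpcr_plate


def table_from_counts(counts_rows, index, columns):
    counts = pd.DataFrame(counts_rows, index=index, columns=columns)
    taxonomy = pd.Series({c: f"Bacteria;Phylum{i};cls" for i, c in enumerate(columns)})
    meta = pd.DataFrame(
        {
            "core": "c1",
            "lake": "MH",
            "zone": ["edge"] * len(index),
            "depth_cm": np.arange(len(index), dtype=float),
        },
        index=index,
    )
    return OtuTable(counts, taxonomy, meta)


class TestRarefy:
    def test_total_exactly_depth_unchanged(self):
        t = table_from_counts([[1000, 2000]], ["s1"], ["a", "b"])
        out = comm.rarefy(t, depth=3000, seed=0)
        assert (out.counts.loc["s1"] == [1000, 2000]).all()

    def test_below_depth_dropped_with_warning(self):
        t = table_from_counts([[1000, 1999], [2000, 2000]], ["lo", "hi"], ["a", "b"])
        with pytest.warns(UserWarning, match="lo"):
            out = comm.rarefy(t, depth=3000, seed=0)
        assert list(out.samples) == ["hi"]

    def test_all_below_depth_errors(self):
        t = table_from_counts([[10, 10]], ["s1"], ["a", "b"])
        with pytest.raises(comm.CommunityError):
            comm.rarefy(t, depth=3000, seed=0)

    def test_totals_exact_and_deterministic(self):
        rng = np.random.default_rng(5)
        t = table_from_counts(
            rng.integers(0, 500, size=(4, 30)) + 120, [f"s{i}" for i in range(4)],
            [f"o{j}" for j in range(30)],
        )
        a = comm.rarefy(t, depth=3000, seed=42)
        b = comm.rarefy(t, depth=3000, seed=42)
        assert (a.counts.sum(axis=1) == 3000).all()
        assert a.counts.equals(b.counts)

    def test_sampling_expectation_matches_hypergeometric(self):
        """Mean rarefied count of an OTU tracks depth * p_i over many draws."""
        counts = np.array([[600, 5400]])
        t = table_from_counts(counts, ["s1"], ["a", "b"])
        draws = np.array(
            [comm.rarefy(t, depth=3000, seed=s).counts.iloc[0, 0] for s in range(200)]
        )
        expect = 3000 * 600 / 6000
        # hypergeometric variance with finite-population correction
        var = 3000 * 0.1 * 0.9 * (6000 - 3000) / (6000 - 1)
        se = np.sqrt(var / 200)
        assert abs(draws.mean() - expect) < 3 * se


class TestAverageReplicates:
    def test_identical_replicates_pass_through(self):
        t = table_from_counts([[10, 20], [10, 20]], ["r1", "r2"], ["a", "b"])
        t.sample_meta.loc[:, "depth_cm"] = 4.0
        out = comm.average_replicates(t, {"r1": "g", "r2": "g"})
        assert (out.counts.loc["g"] == [10, 20]).all()

    def test_pair_mean(self):
        t = table_from_counts([[10, 0], [20, 0]], ["r1", "r2"], ["a", "b"])
        t.sample_meta.loc[:, "depth_cm"] = 4.0
        out = comm.average_replicates(t, {"r1": "g", "r2": "g"})
        assert out.counts.loc["g", "a"] == 15.0

    def test_singletons_kept_and_pairs_collapsed(self):
        """36 samples with 15 pairs collapse to 21 groups."""
        n = 36
        ids = [f"s{i}" for i in range(n)]
        rng = np.random.default_rng(0)
        t = table_from_counts(rng.integers(0, 50, (n, 5)), ids, list("abcde"))
        t.sample_meta.loc[:, "depth_cm"] = 1.0
        pairing = {}
        for k in range(15):  # 30 replicate samples -> 15 pairs
            pairing[ids[2 * k]] = f"g{k}"
            pairing[ids[2 * k + 1]] = f"g{k}"
        out = comm.average_replicates(t, pairing)
        assert len(out.samples) == 21

    def test_triplet_errors(self):
        t = table_from_counts([[1], [2], [3]], ["a", "b", "c"], ["o"])
        t.sample_meta.loc[:, "depth_cm"] = 1.0
        with pytest.raises(comm.CommunityError):
            comm.average_replicates(t, {"a": "g", "b": "g", "c": "g"})


class TestBrayCurtis:
    def test_identical_and_disjoint_samples(self):
        t = table_from_counts([[5, 5, 0], [5, 5, 0], [0, 0, 7]], list("xyz"), list("abc"))
        d = comm.braycurtis(t)
        assert d.loc["x", "y"] == pytest.approx(0.0)
        assert d.loc["x", "z"] == pytest.approx(1.0)

    def test_hand_arithmetic_after_sqrt(self):
        t = table_from_counts([[4, 4], [1, 1]], ["u", "v"], ["a", "b"])
        d = comm.braycurtis(t, transform="sqrt")
        # sqrt gives (2,2) vs (1,1): (1+1)/(3+3) = 1/3
        assert d.loc["u", "v"] == pytest.approx(1.0 / 3.0, rel=1e-12)
        d_raw = comm.braycurtis(t, transform="none")
        assert d_raw.loc["u", "v"] == pytest.approx(6.0 / 10.0, rel=1e-12)

    def test_matrix_properties(self, otu_table):
        rare = comm.rarefy(otu_table, depth=3000, seed=1)
        d = comm.braycurtis(rare)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)
        assert (arr >= 0).all() and (arr <= 1).all()

    def test_all_zero_sample_errors(self):
        t = table_from_counts([[0, 0], [1, 2]], ["z", "s"], ["a", "b"])
        with pytest.raises(comm.CommunityError):
            comm.braycurtis(t)


class TestGuilds:
    def test_single_methanogen_otu_one_percent(self, tiny_table):
        abund, _ = comm.guild_abundance(tiny_table)
        assert abund.loc["s1", "methanogen"] == pytest.approx(1.0)

    def test_relative_abundances_sum_to_100(self, otu_table):
        rel = otu_table.relative_abundance() * 100
        assert np.allclose(rel.sum(axis=1), 100.0, atol=1e-9)

    def test_unmatched_guild_warns_and_zeroes(self, tiny_table):
        guilds = {"ANME": ["ANME-1"]}
        with pytest.warns(UserWarning):
            abund, _ = comm.guild_abundance(tiny_table, guilds)
        assert (abund["ANME"] == 0).all()

    def test_taxon_in_two_guilds_rejected(self, tiny_table):
        guilds = {"g1": ["Methanomicrobiales"], "g2": ["Methanoregulaceae"]}
        with pytest.raises(comm.CommunityError):
            comm.guild_abundance(tiny_table, guilds)

    def test_two_group_t_and_anova_agree(self, otu_table):
        rare = comm.rarefy(otu_table, depth=3000, seed=0)
        _, tests = comm.guild_abundance(rare)
        for t in tests:
            assert t.anova_F == pytest.approx(t.t_stat**2, rel=1e-9)
            assert t.anova_p == pytest.approx(t.t_p, rel=1e-6)

    def test_methanotrophs_confined_to_surface(self, otu_table):
        abund, _ = comm.guild_abundance(otu_table)
        deep = otu_table.sample_meta["depth_cm"] > 6
        assert (abund.loc[deep, "aerobic_methanotroph"] == 0).all()


class TestQpcr:
    def test_standard_copies_arithmetic_oracle(self):
        std = QpcrStandard()
        assert std.genome_mass_g() == pytest.approx(5.058e-15, rel=1e-3)
        assert std.copies_per_uL(1e-2) == pytest.approx(2.77e5, rel=5e-3)

    def test_perfect_dilution_series_r2_one_and_spacing(self):
        cfg = SyntheticConfig(seed=0, qpcr_noise_sd_ct=0.0)
        standards, samples = generate_qpcr_plate(cfg)
        res = comm.quantify_qpcr(samples, standard_table=standards)
        assert res.curve_r2 == pytest.approx(1.0)
        # 10-fold dilutions at 100% efficiency: log2(10) ~ 3.32 cycles apart
        per_dil = standards.groupby("dilution")["ct"].mean().sort_index()
        spacing = np.diff(per_dil.to_numpy())
        assert np.allclose(spacing, -np.log2(10), atol=1e-9)

    def test_round_trip_recovers_true_copies(self):
        cfg = SyntheticConfig(seed=0, qpcr_noise_sd_ct=0.0)
        standards, samples = generate_qpcr_plate(cfg)
        res = comm.quantify_qpcr(samples, standard_table=standards)
        rel_err = (
            res.copies_per_g.to_numpy() / samples["true_copies_per_g"].to_numpy() - 1
        )
        assert np.abs(rel_err).max() < 1e-9

    def test_extrapolation_flagged(self):
        cfg = SyntheticConfig(seed=0, qpcr_noise_sd_ct=0.0)
        standards, samples = generate_qpcr_plate(cfg)
        hot = samples.copy()
        hot.loc[0, "ct"] = 5.0  # far above the standard range
        res = comm.quantify_qpcr(hot, standard_table=standards)
        assert res.flags.loc[hot.loc[0, "sample"], "extrapolated"]

    def test_narrow_standard_series_rejected(self):
        standards = pd.DataFrame({"dilution": [1e-2, 2e-2], "ct": [20.0, 19.0]})
        samples = pd.DataFrame(
            {"sample": ["s"], "ct": [21.0], "template_dilution": [100],
             "sediment_g": [0.25], "elution_uL": [100]}
        )
        with pytest.raises(comm.CommunityError):
            comm.quantify_qpcr(samples, standard_table=standards)


class TestAbsoluteProxy:
    def test_product_arithmetic(self):
        rel = pd.DataFrame({"methanogen": [1.0]}, index=["s"])  # percent
        copies = pd.Series({"s": 1e9})
        zones = pd.Series({"s": "edge"})
        proxy, _ = comm.absolute_guild_proxy(rel, copies, zones)
        assert proxy.loc["s", "methanogen"] == pytest.approx(1e7)

    def test_constant_qpcr_preserves_test_p(self, otu_table):
        rare = comm.rarefy(otu_table, depth=3000, seed=0)
        abund, tests = comm.guild_abundance(rare)
        copies = pd.Series(1e9, index=abund.index)
        _, ptests = comm.absolute_guild_proxy(
            abund, copies, rare.sample_meta["zone"]
        )
        for t, pt in zip(tests, ptests):
            assert pt.t_p == pytest.approx(t.t_p, rel=1e-9)

    def test_unmatched_samples_dropped_with_warning(self, otu_table):
        rare = comm.rarefy(otu_table, depth=3000, seed=0)
        abund, _ = comm.guild_abundance(rare)
        copies = pd.Series(1e9, index=abund.index[:-2])
        with pytest.warns(UserWarning):
            proxy, _ = comm.absolute_guild_proxy(
                abund, copies, rare.sample_meta["zone"]
            )
        assert len(proxy) == len(abund) - 2
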