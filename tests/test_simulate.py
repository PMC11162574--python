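import numpy as np
import pandas as pd
import pytest

from dupevol import cistrans, fate, simulate


class TestFateDataset:
    def test_same_seed_gives_identical_dataset(self):
        a1, f1, p1, t1 = simulate.simulate_fate_dataset(
            simulate.FateSimConfig(seed=5, n_per_fate=10, n_single_copy=50)
        )
        a2, f2, p2, t2 = simulate.simulate_fate_dataset(
            simulate.FateSimConfig(seed=5, n_per_fate=10, n_single_copy=50)
        )
        assert a1.values.equals(a2.values)
        assert f1.values.equals(f2.values)
        assert t1.equals(t2)

    def test_noiseless_fates_recovered_exactly(self):
        # technical noise off; species drift still separates the single-copy
        # calibration set, so E_div is positive and every planted geometry
        # is on the right side of it by construction
        cfg = simulate.FateSimConfig(seed=8, n_per_fate=30, n_single_copy=100,
                                     noise_sd=0.0)
        anc, foc, pairs, truth = simulate.simulate_fate_dataset(cfg)
        d = fate.single_copy_distances(pairs, anc, foc)
        e_div = fate.select_ediv(d)
        calls = fate.classify_triples(pairs, anc, foc, e_div)
        pred = {c.triple_id: c.fate for c in calls}
        assert all(pred[t] == f for t, f in zip(truth.triple_id, truth.fate))

    def test_noiseless_subfunctionalized_raw_sum_matches_ancestor(self):
        cfg = simulate.FateSimConfig(
            seed=8, n_per_fate=20, n_single_copy=50, noise_sd=0.0, species_sd=0.0,
            fates=("subfunctionalized",),
        )
        anc, foc, pairs, _truth = simulate.simulate_fate_dataset(cfg)
        for _, row in pairs.duplicate_triples.iterrows():
            a = 2.0 ** anc.profile(row["ancestral"]) - 1
            p = 2.0 ** foc.profile(row["parent"]) - 1
            c = 2.0 ** foc.profile(row["child"]) - 1
            np.testing.assert_allclose(p + c, a, atol=1e-9)

    def test_offset_not_above_noise_warns(self):
        cfg = simulate.FateSimConfig(seed=1, n_per_fate=2, n_single_copy=40,
                                     noise_sd=1.0, divergence_offset=0.5)
        *_rest, truth = simulate.simulate_fate_dataset(cfg)
        assert "not guaranteed" in truth.attrs["warning"]


class TestCountDataset:
    def test_planted_effects_produce_expected_ratios(self):
        # near-zero dispersion and large counts: ratios converge to the plant
        cfg = simulate.CountSimConfig(
            seed=3, n_pairs=200, dispersion=1e-6, library_size=4e8
        )
        table, truth = simulate.simulate_count_dataset(cfg)
        ratios, _ = cistrans.compute_ratios(table, scale_libraries=False)
        for rp in ratios:
            t = truth.loc[rp.pair_id]
            assert abs(rp.a - (t.cis + t.trans)) < 0.01
            assert abs(rp.b - t.cis) < 0.01

    def test_conserved_pairs_have_no_planted_effect(self):
        cfg = simulate.CountSimConfig(seed=4, n_pairs=100)
        _table, truth = simulate.simulate_count_dataset(cfg)
        vi = truth[truth.category == "VI conserved"]
        assert (vi.cis == 0).all() and (vi.trans == 0).all()

    def test_truth_categories_follow_effect_rules(self):
        cfg = simulate.CountSimConfig(seed=5, n_pairs=300)
        _table, truth = simulate.simulate_count_dataset(cfg)
        for _, row in truth.iterrows():
            a = row.cis + row.trans
            b = row.cis
            sig_a, sig_b, sig_ab = a != 0, b != 0, row.trans != 0
            expected = cistrans.assign_category(
                sig_a, sig_b, sig_ab, int(np.sign(b)), int(np.sign(row.trans))
            )
            assert row.category == expected

    def test_category_mix_must_sum_to_one(self):
        cfg = simulate.CountSimConfig(seed=1, category_mix={"VI conserved": 0.5})
        with pytest.raises(ValueError, match="sum to 1"):
            simulate.simulate_count_dataset(cfg)


class TestMethylome:
    def test_same_seed_gives_identical_calls(self):
        cfg = simulate.MethylomeSimConfig(seed=2, n_genes=20,
                                          genome_length=100_000)
        _g1, c1, _e1, _t1 = simulate.simulate_methylome(cfg)
        _g2, c2, _e2, _t2 = simulate.simulate_methylome(cfg)
        assert c1.equals(c2)

    def test_higher_coverage_reduces_level_variance(self):
        levels = {}
        for cov in (10, 1000):
            cfg = simulate.MethylomeSimConfig(
                seed=6, n_genes=50, genome_length=250_000, coverage=cov
            )
            _genes, calls, _e, _t = simulate.simulate_methylome(cfg)
            lv = calls["n_methylated"] / calls["n_total"]
            levels[cov] = lv.var()
        assert levels[1000] < levels[10]

    def test_genome_too_short_rejected(self):
        cfg = simulate.MethylomeSimConfig(seed=1, n_genes=100, genome_length=10_000)
        with pytest.raises(ValueError, match="too short"):
            simulate.simulate_methylome(cfg)

    def test_both_strands_represented(self):
        cfg = simulate.MethylomeSimConfig(seed=3, n_genes=40,
                                          genome_length=200_000)
        genes, *_ = simulate.simulate_methylome(cfg)
        strands = {g.strand for g in genes}
        assert strands == {"+", "-"}


class TestTransmissionSim:
    def test_all_mass_on_pattern_ii(self):
        freqs = {p: 0.0 for p in
                 ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX")}
        freqs["II"] = 1.0
        cfg = simulate.TransmissionSimConfig(seed=4, n_pairs=100,
                                             pattern_freqs=freqs)
        parental, progeny, truth = simulate.simulate_transmission(cfg)
        assert (truth.pattern == "II").all()
        assert (parental["q"] == 0.5).all() and (parental["sign"] == 0).all()

    def test_group_a_heavy_mix_recovered_within_ci(self):
        from dupevol import transmission as tr

        freqs = {"I": 0.3, "II": 0.3, "III": 0.3,
                 "IV": 0.025, "V": 0.025, "VI": 0.0125, "VII": 0.0125,
                 "VIII": 0.0125, "IX": 0.0125}
        cfg = simulate.TransmissionSimConfig(seed=10, n_pairs=4000,
                                             pattern_freqs=freqs)
        parental, progeny, _truth = simulate.simulate_transmission(cfg)
        s = tr.transmission_summary(tr.classify_pairs(parental, progeny))
        se = np.sqrt(0.9 * 0.1 / 4000)
        assert abs(s["group_proportions"]["A"] - 0.9) < 4 * se

    def test_frequencies_must_sum_to_one(self):
        cfg = simulate.TransmissionSimConfig(seed=1, pattern_freqs={"I": 0.5})
        with pytest.raises(ValueError, match="sum to 1"):
            simulate.simulate_transmission(cfg)
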