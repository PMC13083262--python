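import numpy as np
import pandas as pd
import pytest

from tdmdquant import simulate, stability
from tdmdquant.pipeline import IsoformCountTable
from tdmdquant.stability import (
    ContractError,
    NormalizationError,
    SizeFactors,
    adjust_bh,
    center_on_22nt,
    classify_potentially_sensitive,
    estimate_fold_changes,
    estimate_size_factors,
    filter_expressed,
    isoform_fold_changes,
    short_isoform_test,
    sum_isoforms,
)

DESIGN = {f"ko_{i}": "KO" for i in (1, 2, 3)} | {
    f"ctrl_{i}": "control" for i in (1, 2, 3)
}
SAMPLES = list(DESIGN)


def summed_frame(rows: dict[str, list[int]]) -> pd.DataFrame:
    return pd.DataFrame(rows, index=SAMPLES).T


# --------------------------------------------------------------------------- #
# summing and filtering
# --------------------------------------------------------------------------- #
class TestSumIsoforms:
    def test_matches_brute_force(self, small_table):
        summed = sum_isoforms(small_table)
        for mirna in summed.index[:5]:
            for s in small_table.samples:
                brute = sum(
                    small_table.counts.loc[(m, l), s]
                    for m, l in small_table.counts.index
                    if m == mirna
                )
                assert summed.loc[mirna, s] == brute

    def test_single_isoform_identity(self):
        idx = pd.MultiIndex.from_tuples([("m1", 22)], names=["mirna", "length"])
        t = IsoformCountTable(pd.DataFrame({s: [7] for s in SAMPLES}, index=idx))
        assert (sum_isoforms(t).loc["m1"] == 7).all()

    def test_two_isoforms_sum(self):
        idx = pd.MultiIndex.from_tuples(
            [("m1", 21), ("m1", 22)], names=["mirna", "length"]
        )
        t = IsoformCountTable(pd.DataFrame({s: [5, 7] for s in SAMPLES}, index=idx))
        assert (sum_isoforms(t).loc["m1"] == 12).all()


class TestFilterExpressed:
    def test_two_ko_libraries_and_total_exactly_30_kept(self):
        summed = summed_frame({"m": [6, 6, 0, 6, 6, 6]})
        assert "m" in filter_expressed(summed, DESIGN)

    def test_count_of_exactly_five_not_enough(self):
        # "greater than five" is strict
        summed = summed_frame({"m": [5, 5, 5, 30, 30, 30]})
        assert "m" not in filter_expressed(summed, DESIGN)

    def test_single_high_ko_library_not_enough(self):
        summed = summed_frame({"m": [100, 0, 0, 0, 0, 0]})
        assert "m" not in filter_expressed(summed, DESIGN)

    def test_total_29_dropped(self):
        summed = summed_frame({"m": [6, 6, 6, 6, 5, 0]})
        assert "m" not in filter_expressed(summed, DESIGN)

    def test_bad_design_rejected(self):
        with pytest.raises(ValueError):
            filter_expressed(summed_frame({"m": [9] * 6}), {s: "KO" for s in SAMPLES})


# --------------------------------------------------------------------------- #
# size factors
# --------------------------------------------------------------------------- #
class TestSizeFactors:
    def test_identical_libraries_give_unit_factors(self):
        summed = summed_frame({f"m{i}": [10 * i + 10] * 6 for i in range(5)})
        sf = estimate_size_factors(summed)
        assert np.allclose(sf.factors, 1.0)

    def test_doubled_library_scale_equivariance(self):
        rng = np.random.default_rng(2)
        base = rng.integers(10, 1000, size=50)
        summed = pd.DataFrame({s: base for s in SAMPLES}, index=[f"m{i}" for i in range(50)])
        summed["ko_1"] = summed["ko_1"] * 2
        sf = estimate_size_factors(summed)
        assert sf.factors["ko_1"] == pytest.approx(2 * sf.factors["ko_2"], rel=1e-12)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(3)
        summed = pd.DataFrame(
            rng.integers(1, 500, size=(50, 6)),
            index=[f"m{i}" for i in range(50)],
            columns=SAMPLES,
        )
        sf = estimate_size_factors(summed)
        # independent computation
        ref = summed[(summed > 0).all(axis=1)]
        geo = np.exp(np.log(ref).mean(axis=1))
        for s in SAMPLES:
            assert sf.factors[s] == pytest.approx(float((ref[s] / geo).median()))

    def test_no_all_positive_mirna_raises(self):
        summed = summed_frame({"m1": [1, 0, 1, 1, 1, 1], "m2": [0, 1, 1, 1, 1, 1]})
        with pytest.raises(NormalizationError):
            estimate_size_factors(summed)


# --------------------------------------------------------------------------- #
# fold changes and p-values
# --------------------------------------------------------------------------- #
class TestFoldChanges:
    def unit_sf(self):
        return SizeFactors(pd.Series(1.0, index=SAMPLES))

    def test_equal_group_means_zero_lfc(self):
        summed = summed_frame({"m": [50, 60, 70, 70, 60, 50]})
        fc = estimate_fold_changes(summed, DESIGN, self.unit_sf())
        assert fc.loc["m", "lfc"] == pytest.approx(0.0)

    def test_group_swap_antisymmetry(self):
        summed = summed_frame({"m": [100, 120, 110, 50, 55, 60]})
        swapped = {s: ("control" if g == "KO" else "KO") for s, g in DESIGN.items()}
        a = estimate_fold_changes(summed, DESIGN, self.unit_sf())
        b = estimate_fold_changes(summed, swapped, self.unit_sf())
        assert a.loc["m", "lfc"] == pytest.approx(-b.loc["m", "lfc"])
        assert a.loc["m", "se"] == pytest.approx(b.loc["m", "se"])

    def test_zero_pseudocount_with_zero_group_raises(self):
        summed = summed_frame({"m": [0, 0, 0, 5, 5, 5]})
        with pytest.raises(ValueError):
            estimate_fold_changes(summed, DESIGN, self.unit_sf(), pseudocount=0.0)

    def test_monte_carlo_recovery_of_unit_lfc(self):
        # true lfc 1, base 1000, dispersion 0.05, 3v3, >=200 simulated miRNAs
        d = simulate.make_mirna_dictionary(250, 0.0, seed=30)
        from tests.test_simulate import uniform_truth

        truth = uniform_truth(d, base=1000.0, lfc_tdmd=1.0, dispersion=0.05, seed=31)
        table = simulate.simulate_isoform_counts(d, truth)
        summed = sum_isoforms(table)
        matures = [s.name for s in d.matures()]
        fc = estimate_fold_changes(summed.loc[matures], DESIGN, self.unit_sf())
        assert len(fc) >= 200
        assert fc["lfc"].mean() == pytest.approx(1.0, abs=0.1)


class TestAdjustBH:
    def test_single_p_unchanged(self):
        assert adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_hand_computed_example(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert np.allclose(adjust_bh([0.04] * 5), 0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])


# --------------------------------------------------------------------------- #
# classification
# --------------------------------------------------------------------------- #
class TestClassification:
    def frame(self, lfc, se, padj):
        return pd.DataFrame(
            {"lfc": [lfc], "se": [se], "p": [padj], "padj": [padj]}, index=["m"]
        )

    def passenger(self, lfc, se):
        return pd.DataFrame(
            {"passenger_lfc": [lfc], "passenger_se": [se]}, index=["m"]
        )

    def test_padj_flag(self):
        out = classify_potentially_sensitive(self.frame(0.5, 0.1, 0.04))
        assert bool(out.loc["m", "potentially_sensitive_padj"])
        out = classify_potentially_sensitive(self.frame(-0.5, 0.1, 0.04))
        assert not bool(out.loc["m", "potentially_sensitive_padj"])

    def test_passenger_separation_true(self):
        # 1.0 - 0.2 = 0.8 > 0.1 + 0.2 = 0.3
        out = classify_potentially_sensitive(
            self.frame(1.0, 0.2, 0.5), self.passenger(0.1, 0.2)
        )
        assert bool(out.loc["m", "potentially_sensitive_passenger"])

    def test_passenger_separation_false(self):
        # 0.3 - 0.3 = 0.0 < 0.1 + 0.2 = 0.3
        out = classify_potentially_sensitive(
            self.frame(0.3, 0.3, 0.5), self.passenger(0.1, 0.2)
        )
        assert not bool(out.loc["m", "potentially_sensitive_passenger"])

    def test_external_annotation_flag_and_union(self):
        out = classify_potentially_sensitive(
            self.frame(0.1, 0.5, 0.9), external_list=["m"]
        )
        assert bool(out.loc["m", "potentially_sensitive_annotation"])
        assert bool(out.loc["m", "excluded"])

    def test_missing_passenger_warns_and_leaves_flag_false(self):
        import warnings

        summed = summed_frame({"m": [50, 60, 70, 70, 60, 50]})
        sf = SizeFactors(pd.Series(1.0, index=SAMPLES))
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            ps = stability.passenger_fold_changes(
                summed, DESIGN, sf, {"m": ["absent-passenger"]}
            )
        assert any("passenger" in str(w.message) for w in rec)
        assert np.isnan(ps.loc["m", "passenger_lfc"])


# --------------------------------------------------------------------------- #
# isoform level
# --------------------------------------------------------------------------- #
class TestIsoformLevel:
    def iso_table(self):
        rng = np.random.default_rng(7)
        idx = pd.MultiIndex.from_tuples(
            [(f"m{i}", l) for i in range(10) for l in (15, 22)],
            names=["mirna", "length"],
        )
        return IsoformCountTable(
            pd.DataFrame(rng.integers(20, 300, size=(20, 6)), index=idx, columns=SAMPLES)
        )

    def test_provenance_contract(self):
        t = self.iso_table()
        bad = SizeFactors(pd.Series(1.0, index=SAMPLES), provenance="isoform")
        with pytest.raises(ContractError):
            isoform_fold_changes(t, bad, DESIGN)

    def test_excluded_mirnas_dropped(self):
        t = self.iso_table()
        sf = SizeFactors(pd.Series(1.0, index=SAMPLES))
        iso = isoform_fold_changes(t, sf, DESIGN, excluded=["m0", "m3"])
        assert "m0" not in iso.index.get_level_values("mirna")
        assert "m3" not in iso.index.get_level_values("mirna")

    def test_matches_per_cell_recomputation(self):
        t = self.iso_table()
        sf = SizeFactors(pd.Series(1.0, index=SAMPLES))
        iso = isoform_fold_changes(t, sf, DESIGN)
        ko = [s for s, g in DESIGN.items() if g == "KO"]
        ctrl = [s for s, g in DESIGN.items() if g == "control"]
        for key in iso.index[:6]:
            row = t.counts.loc[key]
            expect = np.log2((row[ko].mean() + 0.5) / (row[ctrl].mean() + 0.5))
            assert iso.loc[key, "lfc"] == pytest.approx(expect)

    def test_single_length_equals_summed_level(self):
        idx = pd.MultiIndex.from_tuples(
            [(f"m{i}", 22) for i in range(5)], names=["mirna", "length"]
        )
        rng = np.random.default_rng(8)
        t = IsoformCountTable(
            pd.DataFrame(rng.integers(50, 500, size=(5, 6)), index=idx, columns=SAMPLES)
        )
        sf = SizeFactors(pd.Series(1.0, index=SAMPLES))
        iso = isoform_fold_changes(t, sf, DESIGN)
        summed_fc = estimate_fold_changes(sum_isoforms(t), DESIGN, sf)
        assert np.allclose(
            iso["lfc"].to_numpy(), summed_fc["lfc"].to_numpy()
        )


class TestCentering:
    def iso(self, entries):
        idx = pd.MultiIndex.from_tuples(
            [k for k, _ in entries], names=["mirna", "length"]
        )
        return pd.DataFrame({"lfc": [v for _, v in entries]}, index=idx)

    def test_median_subtracted(self):
        iso = self.iso(
            [(("a", 22), 0.1), (("b", 22), 0.3), (("c", 22), 0.5), (("a", 15), 1.0)]
        )
        out = center_on_22nt(iso)
        assert out.loc[("a", 15), "centered_lfc"] == pytest.approx(0.7)
        med22 = out[out.index.get_level_values("length") == 22]["centered_lfc"].median()
        assert med22 == 0.0

    def test_constant_lfc_centers_to_zero(self):
        iso = self.iso([(("a", 22), 0.4), (("b", 22), 0.4), (("a", 16), 0.4)])
        assert (center_on_22nt(iso)["centered_lfc"] == 0.0).all()

    def test_no_22nt_entries_raise(self):
        iso = self.iso([(("a", 15), 0.4)])
        with pytest.raises(ValueError):
            center_on_22nt(iso)


class TestShortIsoformTest:
    def iso(self, values, length=15):
        idx = pd.MultiIndex.from_tuples(
            [(f"m{i}", length) for i in range(len(values))], names=["mirna", "length"]
        )
        return pd.DataFrame({"centered_lfc": values}, index=idx)

    def test_all_zero_null(self):
        res = short_isoform_test(self.iso([0.0] * 10))
        assert res.p >= 0.5

    def test_sign_flip_reverses_direction(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(0.5, 0.2, size=30)
        up = short_isoform_test(self.iso(list(vals)))
        down = short_isoform_test(self.iso(list(-vals)))
        assert up.p < 0.05
        assert down.p >= 0.5
        assert up.effect_median == pytest.approx(-down.effect_median)

    def test_power_on_simulated_short_effect(self):
        # lfc_short +0.5 across >=100 species gives a detectable signal
        from tests.test_simulate import uniform_truth

        hits = 0
        d = simulate.make_mirna_dictionary(60, 0.0, seed=40)
        for seed in range(10):
            truth = uniform_truth(d, base=3000.0, lfc_short=0.5, seed=100 + seed)
            table = simulate.simulate_isoform_counts(d, truth)
            res = stability.analyze(table, truth.design)
            if res.short_test is not None and res.short_test.p < 0.05:
                hits += 1
        assert hits >= 9

    def test_too_few_short_isoforms_raise(self):
        with pytest.raises(ValueError):
            short_isoform_test(self.iso([0.1, 0.2], length=15))
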