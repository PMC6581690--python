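"""Positive calling, PM/MM ratios, normalization, quantitation, statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fgarray.errors import ContractError, DomainError
from fgarray.hyb_sim import (
    CommunityMix,
    HybModel,
    MixComponent,
    SignalMatrix,
    simulate_samples,
)
from fgarray.signals import (
    community_stats,
    compute_calls,
    detection_table,
    fit_quantitation,
    normalize_cors,
    pm_mm_calls,
    relative_difference,
)


def make_matrix(rows):
    """rows: (probe_id, probe_class, subarray, sample, replicate, intensity)"""
    return SignalMatrix(
        data=pd.DataFrame(
            rows,
            columns=["probe_id", "probe_class", "subarray", "sample",
                     "replicate", "intensity"],
        )
    )


def simple_array(values, negs=(100.0, 110.0, 90.0), sample="s1", rep=1):
    rows = [(f"n{i}", "negative_control", 0, sample, rep, v) for i, v in enumerate(negs)]
    rows += [("cors_0", "cors_control", 0, sample, rep, 5000.0)]
    rows += [
        (pid, "sequence_specific", 0, sample, rep, v) for pid, v in values.items()
    ]
    return rows


class TestComputeCalls:
    def test_raw_at_background_mean_not_positive(self):
        sm = make_matrix(simple_array({"p1": 100.0}))
        calls = compute_calls(sm)
        row = calls.data[calls.data["probe_id"] == "p1"].iloc[0]
        assert row["snr"] == pytest.approx(0.0)
        assert not row["positive"]
        assert row["net"] == pytest.approx(0.0)

    def test_snr_exactly_two_not_positive(self):
        negs = (90.0, 100.0, 110.0)  # mean 100, sd 10
        sm = make_matrix(simple_array({"p1": 120.0}, negs=negs))
        row = compute_calls(sm).data.query("probe_id == 'p1'").iloc[0]
        assert row["snr"] == pytest.approx(2.0)
        assert not row["positive"]

    def test_strong_signal_positive_in_all_replicates(self, present_absent_signals):
        sm, _ = present_absent_signals
        calls = compute_calls(sm)
        pm = calls.data[
            (calls.data["probe_class"] == "pm_control")
            & (calls.data["sample"] == "present")
        ]
        assert pm["positive"].all()

    def test_net_intensity_floored_at_zero(self):
        sm = make_matrix(simple_array({"p1": 10.0}))
        row = compute_calls(sm).data.query("probe_id == 'p1'").iloc[0]
        assert row["net"] == 0.0

    def test_zero_background_sd_falls_back_to_mean_rule(self, caplog):
        sm = make_matrix(simple_array({"p1": 150.0, "p2": 90.0}, negs=(100.0, 100.0)))
        calls = compute_calls(sm)
        p1 = calls.data.query("probe_id == 'p1'").iloc[0]
        p2 = calls.data.query("probe_id == 'p2'").iloc[0]
        assert math.isnan(p1["snr"]) and p1["positive"]
        assert not p2["positive"]
        assert "zero background sd" in caplog.text

    def test_subarray_without_negatives_is_contract_error(self):
        rows = [("p1", "sequence_specific", 0, "s1", 1, 200.0),
                ("n0", "negative_control", 0, "s1", 1, 100.0)]
        with pytest.raises(ContractError):
            compute_calls(make_matrix(rows))

    def test_calling_monotone_in_raw_intensity(self):
        sm = make_matrix(simple_array({"p1": 140.0, "p2": 90.0}))
        before = compute_calls(sm).data.set_index("probe_id")["positive"]
        bumped = sm.data.copy()
        bumped.loc[bumped["probe_id"] == "p2", "intensity"] += 500.0
        after = compute_calls(make_matrix(bumped.values.tolist())).data.set_index(
            "probe_id"
        )["positive"]
        for pid in ("p1", "p2"):
            assert after[pid] >= before[pid]


class TestPmMmCalls:
    def test_equal_nets_ratio_one_not_positive(self, present_absent_signals):
        sm, pairs = present_absent_signals
        calls = compute_calls(sm)
        # overwrite one pair's nets to be equal: ratio must be exactly 1
        df = calls.data
        pm_id, mm_id = pairs[0].pm.probe_id, pairs[0].mm.probe_id
        df.loc[df["probe_id"].isin([pm_id, mm_id]), "net"] = 500.0
        out = pm_mm_calls(calls, [pairs[0]])
        assert (out["ratio"] == 1.0).all()
        assert not out["ratio_positive"].any()

    def test_present_targets_have_large_positive_ratios(self, present_absent_signals):
        sm, pairs = present_absent_signals
        calls = compute_calls(sm)
        out = pm_mm_calls(calls, pairs)
        present = out[out["sample"] == "present"]
        assert (present["ratio"] > 1.3).mean() > 0.99
        assert present["ratio"].median() > 5

    def test_absent_targets_not_called(self, present_absent_signals):
        sm, pairs = present_absent_signals
        calls = compute_calls(sm)
        out = pm_mm_calls(calls, pairs)
        absent = out[out["sample"] == "absent"]
        assert absent["ratio_positive"].mean() < 0.05

    def test_missing_mate_is_pairing_error(self, present_absent_signals):
        from fgarray.errors import PairingError
        from fgarray.probe_design import Probe

        sm, pairs = present_absent_signals
        calls = compute_calls(sm)
        ghost = Probe("ghost", "ACGT" * 13 if False else "ACGTACGTAC" * 5, "pm_control")
        with pytest.raises(PairingError):
            pm_mm_calls(calls, [(ghost, pairs[0].mm)])


class TestNormalizeCors:
    def test_recovers_scaled_array(self, present_absent_signals):
        sm, _ = present_absent_signals
        df = sm.data[sm.data["sample"] == "present"].copy()
        scaled = df.copy()
        scaled["sample"] = "present_x3"
        scaled["intensity"] *= 3.0
        both = SignalMatrix(data=pd.concat([df, scaled], ignore_index=True))
        norm = normalize_cors(both)
        a = norm.data[norm.data["sample"] == "present"].set_index(
            ["probe_id", "replicate"]
        )["intensity"]
        b = norm.data[norm.data["sample"] == "present_x3"].set_index(
            ["probe_id", "replicate"]
        )["intensity"]
        assert np.allclose(a.sort_index(), b.sort_index())

    def test_single_array_unchanged(self):
        sm = make_matrix(simple_array({"p1": 800.0}))
        norm = normalize_cors(sm)
        assert np.allclose(norm.data["intensity"], sm.data["intensity"])

    def test_idempotent(self, present_absent_signals):
        sm, _ = present_absent_signals
        once = normalize_cors(sm)
        twice = normalize_cors(once)
        assert np.allclose(once.data["intensity"], twice.data["intensity"])

    def test_preserves_within_array_ratios(self, present_absent_signals):
        sm, _ = present_absent_signals
        norm = normalize_cors(sm)
        raw = sm.data.set_index(["probe_id", "sample", "replicate"])["intensity"]
        scaled = norm.data.set_index(["probe_id", "sample", "replicate"])["intensity"]
        factor = scaled / raw
        per_array = factor.groupby(level=["sample", "replicate"]).agg(["min", "max"])
        assert np.allclose(per_array["min"], per_array["max"])

    def test_missing_cors_is_contract_error(self):
        rows = [r for r in simple_array({"p1": 500.0}) if r[1] != "cors_control"]
        with pytest.raises(ContractError):
            normalize_cors(make_matrix(rows))


@pytest.fixture(scope="module")
def dilution_series(pm_mm_layout, pools):
    layout, _ = pm_mm_layout
    model = HybModel(noise_cv=0.0, background_sd=0.0)
    masses = {f"m{i}": m for i, m in enumerate([0.5, 1.0, 5.0, 10.0, 50.0])}
    mixes = {
        s: CommunityMix(components=[MixComponent("targets", m)])
        for s, m in masses.items()
    }
    sm = simulate_samples(layout, mixes, pools.pools, model, n_replicates=3, seed=31)
    return sm, masses


class TestFitQuantitation:
    def test_noise_free_series_fits_slope_one_r_one(self, dilution_series):
        sm, masses = dilution_series
        # noise-free background has sd 0: call with the mean-rule fallback
        fit = fit_quantitation(sm, masses)
        fitted = fit.per_probe
        assert len(fitted) > 0
        assert np.allclose(fitted["pearson_r"], 1.0)
        assert np.allclose(fitted["slope"], 1.0, atol=1e-6)
        assert fit.total_r == pytest.approx(1.0)

    def test_saturated_point_flattens_slope_and_flags(self, pm_mm_layout, pools):
        layout, _ = pm_mm_layout
        model = HybModel(noise_cv=0.0, background_sd=0.0, saturation=30_000.0)
        masses = {"a": 10.0, "b": 100.0, "c": 1000.0}
        mixes = {
            s: CommunityMix(components=[MixComponent("targets", m)])
            for s, m in masses.items()
        }
        sm = simulate_samples(layout, mixes, pools.pools, model, 3, seed=32)
        fit = fit_quantitation(sm, masses, saturation=model.saturation)
        sat = fit.per_probe[fit.per_probe["probe_id"].isin(fit.saturated_flagged)]
        assert len(sat) > 0
        assert (sat["slope"] < 1.0 - 1e-6).all()

    def test_shuffled_masses_collapse_correlation(self, dilution_series):
        sm, masses = dilution_series
        rng = np.random.default_rng(33)
        rs = []
        for _ in range(5):
            vals = list(masses.values())
            rng.shuffle(vals)
            shuffled = dict(zip(masses.keys(), vals))
            fit = fit_quantitation(sm, shuffled)
            rs.append(fit.per_probe["pearson_r"].abs().mean())
        true_fit = fit_quantitation(sm, masses)
        assert np.mean(rs) < true_fit.per_probe["pearson_r"].mean()
        assert np.mean(rs) < 0.9

    def test_degenerate_series_rejected(self, dilution_series):
        sm, masses = dilution_series
        with pytest.raises(DomainError):
            fit_quantitation(sm, {s: 5.0 for s in masses})
        with pytest.raises(DomainError):
            fit_quantitation(sm, {"a": 1.0, "b": 2.0})


class TestRelativeDifference:
    @pytest.mark.parametrize(
        "m1,m2,expected",
        [(3.0, 4.0, -0.25), (4.0, 3.0, 0.25), (5.0, 5.0, 0.0), (0.0, 0.0, 0.0)],
    )
    def test_known_values(self, m1, m2, expected):
        assert relative_difference(m1, m2) == pytest.approx(expected)

    def test_bounded_and_antisymmetric(self):
        rng = np.random.default_rng(34)
        for _ in range(100):
            m1, m2 = rng.uniform(0, 100, 2)
            rd = relative_difference(m1, m2)
            assert -1.0 <= rd <= 1.0
            assert rd == pytest.approx(-relative_difference(m2, m1))

    def test_negative_means_rejected(self):
        with pytest.raises(DomainError):
            relative_difference(-1.0, 2.0)


def exact_utest_pvalue(a, b):
    """Exhaustive permutation null of the Mann-Whitney U statistic
    (no ties): two-sided p = P(min(U, n1*n2-U) <= observed min)."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(group1, group2):
        return sum(1 for x in group1 for y in group2 if x > y)

    obs = u_stat(a, b)
    obs_min = min(obs, n1 * len(b) - obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(g1, g2)
        if min(u, n1 * len(g2) - u) <= obs_min:
            count += 1
        total += 1
    return count / total


class TestUTest:
    def test_scipy_exact_matches_enumeration(self):
        rng = np.random.default_rng(35)
        for n1, n2 in [(3, 3), (4, 3), (4, 4), (5, 4)]:
            for _ in range(5):
                a = rng.normal(0, 1, n1)
                b = rng.normal(0.5, 1, n2)
                p_scipy = sps.mannwhitneyu(a, b, alternative="two-sided",
                                           method="exact").pvalue
                assert p_scipy == pytest.approx(exact_utest_pvalue(a, b))


@pytest.fixture(scope="module")
def grouped_signals(pm_mm_layout, pools):
    """Two groups of 4 samples; group 'hi' hybridized with 4x the DNA.

    Four per group because the exact two-sided U test cannot go below
    p = 0.1 with 3 vs 3 observations.
    """
    layout, _ = pm_mm_layout
    model = HybModel(noise_cv=0.15)
    mixes = {}
    for i in range(4):
        mixes[f"lo{i}"] = CommunityMix(components=[MixComponent("targets", 10.0)])
        mixes[f"hi{i}"] = CommunityMix(components=[MixComponent("targets", 40.0)])
    sm = simulate_samples(layout, mixes, pools.pools, model, n_replicates=3, seed=36)
    labels = {s: ("hi" if s.startswith("hi") else "lo") for s in mixes}
    return sm, labels


class TestCommunityStats:
    def test_uniform_abundances_give_log_richness_and_even(self):
        # craft calls directly: 4 genes at identical abundance
        rows = []
        for rep in (1, 2, 3):
            rows += simple_array(
                {f"g{i}": 1100.0 for i in range(4)}, rep=rep
            )
        sm = make_matrix(rows)
        calls = compute_calls(sm)
        res = community_stats(calls, sm, {"s1": "G"})
        row = res["per_sample"].iloc[0]
        assert row["richness"] == 4
        assert row["shannon"] == pytest.approx(math.log(4), rel=1e-3)
        assert row["evenness"] == pytest.approx(1.0, rel=1e-3)

    def test_zero_richness_reports_missing(self):
        rows = []
        for rep in (1, 2, 3):
            rows += simple_array({"g0": 100.0}, rep=rep)
        sm = make_matrix(rows)
        calls = compute_calls(sm)
        res = community_stats(calls, sm, {"s1": "G"})
        row = res["per_sample"].iloc[0]
        assert row["richness"] == 0
        assert math.isnan(row["shannon"]) and math.isnan(row["evenness"])

    def test_group_contrast_detects_abundance_shift(self, grouped_signals):
        sm, labels = grouped_signals
        calls = compute_calls(sm)
        norm = normalize_cors(sm)
        res = community_stats(calls, norm, labels)
        per_gene = res["per_gene"]
        assert not per_gene.empty
        pm_rows = per_gene[per_gene["probe_id"].str.contains(":")]
        # hi group mean ~4x lo: relative difference ~ +/-0.75 and mostly significant
        assert pm_rows["relative_difference"].abs().median() > 0.5
        assert pm_rows["significant"].mean() > 0.8

    def test_relative_difference_sign_follows_group_order(self, grouped_signals):
        sm, labels = grouped_signals
        calls = compute_calls(sm)
        norm = normalize_cors(sm)
        per_gene = community_stats(calls, norm, labels)["per_gene"]
        # groups sorted alphabetically: group1='hi', group2='lo', hi larger
        consistent = (per_gene["mean1"] > per_gene["mean2"]) == (
            per_gene["relative_difference"] > 0
        )
        assert consistent[per_gene["relative_difference"] != 0].all()

    def test_small_groups_skip_tests_with_warning(self, caplog):
        rows = []
        for sample in ("s1", "s2"):
            for rep in (1, 2, 3):
                rows += simple_array({"g0": 1500.0}, sample=sample, rep=rep)
        sm = make_matrix(rows)
        calls = compute_calls(sm)
        res = community_stats(calls, sm, {"s1": "A", "s2": "B"})
        assert res["per_gene"].empty
        assert "U test skipped" in caplog.text


def test_detection_majority_rule(present_absent_signals):
    sm, _ = present_absent_signals
    calls = compute_calls(sm)
    det = detection_table(calls)
    pm_present = det[
        (det["probe_class"] == "pm_control") & (det["sample"] == "present")
    ]
    assert pm_present["detected"].all()
    neg = det[det["probe_class"] == "negative_control"]
    assert not neg["detected"].any()
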