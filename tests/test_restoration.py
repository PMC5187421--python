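"""Restoration index: oracle equivalence, endpoint/symmetry properties,
electrode selection, bootstrap CI calibration, group aggregation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from phonrestore.restoration import (
    aggregate_ri,
    bootstrap_ci_criteria,
    restoration_index,
    select_electrodes,
)
from conftest import synthetic_epochs


def brute_force_ri(data, trials, channel_idx, half):
    """Independent loop-based recomputation of D0/D1/D2 and RI."""
    n_e = len(channel_idx)
    n_f = data.shape[1]
    cond = trials["condition"].to_numpy()
    perc = trials["reported_percept"].to_numpy()
    m1 = data[channel_idx][:, :, cond == "orig1"].mean(axis=2)
    m2 = data[channel_idx][:, :, cond == "orig2"].mean(axis=2)
    out = np.full((n_e, n_f, 2), np.nan)
    for p in (1, 2):
        sel = (cond == "noise") & (perc == p)
        if not sel.any():
            continue
        mn = data[channel_idx][:, :, sel].mean(axis=2)
        for e in range(n_e):
            for j in range(n_f):
                lo, hi = max(0, j - half), min(n_f, j + half + 1)
                d1 = np.sqrt(((mn[e, lo:hi] - m1[e, lo:hi]) ** 2).sum())
                d2 = np.sqrt(((mn[e, lo:hi] - m2[e, lo:hi]) ** 2).sum())
                d0 = np.sqrt(((m1[e, lo:hi] - m2[e, lo:hi]) ** 2).sum())
                if d0 > 0:
                    out[e, j, p - 1] = (d2 - d1) / d0
    return out


def _selection_for(ep, trials, ids):
    from phonrestore.restoration import ElectrodeSelection

    return ElectrodeSelection(
        word_pair_id="wp0",
        selected=list(ids),
        zscore_threshold=0.0,
        window=(0.3, 0.7),
        max_abs_diff=pd.Series(1.0, index=list(ids)),
    )


class TestRestorationIndexOracle:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            ep, trials = synthetic_epochs(n_e=3, n_f=20, n_per_cell=3, rng=rng)
            sel = _selection_for(ep, trials, ep.channel_ids)
            res = restoration_index(ep, trials, sel, smooth_window_frames=5)
            expected = brute_force_ri(ep.data, trials, [0, 1, 2], half=2)
            np.testing.assert_allclose(res.ri, expected, atol=1e-10)

    def test_ri_bounded_by_triangle_inequality(self):
        ep, trials = synthetic_epochs(rng=np.random.default_rng(3))
        sel = _selection_for(ep, trials, ep.channel_ids)
        res = restoration_index(ep, trials, sel)
        assert np.nanmax(np.abs(res.ri)) <= 1 + 1e-12


class TestRiEndpoints:
    def _planted(self, copy_from):
        ep, trials = synthetic_epochs(n_e=2, n_f=40, rng=np.random.default_rng(5))
        cond = trials["condition"].to_numpy()
        perc = trials["reported_percept"].to_numpy()
        m = {c: ep.data[:, :, cond == c].mean(axis=2) for c in ("orig1", "orig2")}
        target = {
            "orig1": m["orig1"],
            "orig2": m["orig2"],
            "mid": 0.5 * (m["orig1"] + m["orig2"]),
        }[copy_from]
        # force the noise-percept-1 trial mean to the target trace exactly
        sel_noise = (cond == "noise") & (perc == 1)
        idx = np.flatnonzero(sel_noise)
        cur = ep.data[:, :, idx].mean(axis=2)
        ep.data[:, :, idx] += (target - cur)[:, :, None]
        sel = _selection_for(ep, trials, ep.channel_ids)
        return restoration_index(ep, trials, sel)

    def test_noise_equal_orig1_gives_plus_one(self):
        res = self._planted("orig1")
        assert np.allclose(res.ri[:, :, 0], 1.0, atol=1e-9)

    def test_noise_equal_orig2_gives_minus_one(self):
        res = self._planted("orig2")
        assert np.allclose(res.ri[:, :, 0], -1.0, atol=1e-9)

    def test_noise_at_midpoint_gives_zero(self):
        res = self._planted("mid")
        assert np.allclose(res.ri[:, :, 0], 0.0, atol=1e-9)

    def test_antisymmetry_under_label_swap(self):
        ep, trials = synthetic_epochs(rng=np.random.default_rng(7))
        sel = _selection_for(ep, trials, ep.channel_ids)
        res = restoration_index(ep, trials, sel)
        swapped = trials.copy()
        swapped["condition"] = swapped["condition"].map(
            {"orig1": "orig2", "orig2": "orig1", "noise": "noise"}
        )
        res_sw = restoration_index(ep, swapped, sel)
        np.testing.assert_allclose(res_sw.ri, -res.ri, atol=1e-12)

    def test_positive_scale_invariance(self):
        ep, trials = synthetic_epochs(rng=np.random.default_rng(8))
        sel = _selection_for(ep, trials, ep.channel_ids)
        res = restoration_index(ep, trials, sel)
        ep.data *= 3.7
        res_scaled = restoration_index(ep, trials, sel)
        np.testing.assert_allclose(res_scaled.ri, res.ri, atol=1e-12)

    def test_zero_d0_yields_nan_not_inf(self):
        ep, trials = synthetic_epochs(n_e=1, rng=np.random.default_rng(9))
        cond = trials["condition"].to_numpy()
        ep.data[:, :, cond == "orig2"] = ep.data[:, :, cond == "orig1"].mean(
            axis=2, keepdims=True
        )
        ep.data[:, :, cond == "orig1"] = ep.data[:, :, cond == "orig2"]
        sel = _selection_for(ep, trials, ep.channel_ids)
        res = restoration_index(ep, trials, sel)
        assert np.isnan(res.ri).all()
        assert not np.isinf(res.ri).any()


class TestSelectElectrodes:
    def test_planted_difference_selected(self):
        ep, trials = synthetic_epochs(n_e=5, rng=np.random.default_rng(1))
        cond = trials["condition"].to_numpy()
        win = (ep.times >= 0.3) & (ep.times < 0.7)
        ep.data[2][np.ix_(win, cond == "orig1")] += 3.0
        sel = select_electrodes(ep, trials, "wp0", zscore_threshold=1.5)
        assert sel.selected == ["e002"]
        # direct recomputation of the difference trace
        diff = np.abs(
            ep.data[2][:, cond == "orig1"].mean(1) - ep.data[2][:, cond == "orig2"].mean(1)
        )
        assert sel.max_abs_diff["e002"] == pytest.approx(diff[win].max())

    def test_zero_threshold_selects_all(self):
        ep, trials = synthetic_epochs(rng=np.random.default_rng(2))
        sel = select_electrodes(ep, trials, "wp0", zscore_threshold=0.0)
        assert sel.selected == ep.channel_ids

    def test_identical_originals_select_nothing(self):
        ep, trials = synthetic_epochs(rng=np.random.default_rng(3))
        cond = trials["condition"].to_numpy()
        ep.data[:, :, cond == "orig2"] = ep.data[:, :, cond == "orig1"]
        with pytest.warns(UserWarning, match="no electrode"):
            sel = select_electrodes(ep, trials, "wp0", zscore_threshold=1.5)
        assert sel.selected == []


class TestBootstrapCi:
    def test_null_disjoint_rate_calibrated(self):
        # same-distribution conditions: "!=" rate should respect the CI level
        ep, trials = synthetic_epochs(n_e=4, n_f=250, n_per_cell=12,
                                      rng=np.random.default_rng(10))
        sel = _selection_for(ep, trials, ep.channel_ids)
        crit = bootstrap_ci_criteria(ep, trials, sel, n_boot=200, seed=1)
        n_cells = crit.orig_differ.size
        assert n_cells >= 1000
        rate = crit.orig_differ.mean()
        nominal = 0.01
        se = np.sqrt(nominal * (1 - nominal) / n_cells)
        assert rate <= nominal + 3 * se

    def test_overwhelming_separation_all_disjoint(self):
        ep, trials = synthetic_epochs(rng=np.random.default_rng(11))
        cond = trials["condition"].to_numpy()
        ep.data[:, :, cond == "orig1"] += 10.0
        sel = _selection_for(ep, trials, ep.channel_ids)
        crit = bootstrap_ci_criteria(ep, trials, sel, n_boot=200, seed=2)
        assert crit.orig_differ.all()

    def test_seeded_reproducibility(self):
        ep, trials = synthetic_epochs(rng=np.random.default_rng(12))
        sel = _selection_for(ep, trials, ep.channel_ids)
        a = bootstrap_ci_criteria(ep, trials, sel, n_boot=150, seed=5)
        b = bootstrap_ci_criteria(ep, trials, sel, n_boot=150, seed=5)
        assert np.array_equal(a.orig_differ, b.orig_differ)
        assert np.array_equal(a.noise1_matches_orig1, b.noise1_matches_orig1)

    def test_small_n_boot_warns(self):
        ep, trials = synthetic_epochs(rng=np.random.default_rng(13))
        sel = _selection_for(ep, trials, ep.channel_ids)
        with pytest.warns(UserWarning, match="n_boot"):
            bootstrap_ci_criteria(ep, trials, sel, n_boot=50, seed=0)

    def test_restoration_criteria_on_planted_match(self):
        # noise-p1 tracks orig1; noise-p2 tracks orig2 during the response
        ep, trials = synthetic_epochs(n_e=2, rng=np.random.default_rng(14))
        cond = trials["condition"].to_numpy()
        perc = trials["reported_percept"].to_numpy()
        win = np.flatnonzero((ep.times >= 0.3) & (ep.times < 0.6))
        for mask in (cond == "orig1", (cond == "noise") & (perc == 1)):
            ep.data[np.ix_(range(ep.data.shape[0]), win, np.flatnonzero(mask))] += 8.0
        sel = _selection_for(ep, trials, ep.channel_ids)
        crit = bootstrap_ci_criteria(ep, trials, sel, n_boot=300, seed=3)
        w = win[5:-5]
        assert crit.orig_differ[:, w].all()
        assert crit.noise1_matches_orig1[:, w].all()
        assert crit.noise2_matches_orig2[:, w].all()


class TestAggregateRi:
    def test_identical_percept_traces_never_significant(self):
        ep, trials = synthetic_epochs(rng=np.random.default_rng(20))
        cond = trials["condition"].to_numpy()
        perc = trials["reported_percept"].to_numpy()
        # copy percept-2 noise trials from percept-1 ones -> identical means
        i1 = np.flatnonzero((cond == "noise") & (perc == 1))
        i2 = np.flatnonzero((cond == "noise") & (perc == 2))
        ep.data[:, :, i2] = ep.data[:, :, i1]
        sel = _selection_for(ep, trials, ep.channel_ids)
        res = restoration_index(ep, trials, sel)
        assert np.allclose(np.nan_to_num(res.abs_dri), 0.0, atol=1e-12)
        group = aggregate_ri([res], [True])
        assert not group.sig.any()

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            aggregate_ri([], [])

    def test_analysis_window_frame_count(self):
        ep, trials = synthetic_epochs(n_f=160, rng=np.random.default_rng(21))
        sel = _selection_for(ep, trials, ep.channel_ids)
        res = restoration_index(ep, trials, sel)
        group = aggregate_ri([res], [True])
        assert group.times.size == 91  # -0.3..0.6 s at 100 Hz


class TestGainMonotonicity:
    def test_stronger_restoration_gain_raises_post_latency_dri(self):
        """Raising restoration_gain (same seed) does not decrease the mean
        post-latency |dRI| on the selected electrodes."""
        from conftest import preprocess_chain, small_config
        from phonrestore.pipeline import simulate_dataset

        means = []
        for gain in (0.3, 0.8):
            cfg = small_config(seed=21, n_trials_per_condition=24,
                               n_contrast_electrodes=12, restoration_gain=gain)
            rec, trials, electrodes, triplets, fm, _ = simulate_dataset(cfg)
            ep = preprocess_chain(rec, trials, electrodes)
            sel = select_electrodes(ep, trials, "wp0", 1.5)
            res = restoration_index(ep, trials, sel)
            times = res.t0 + np.arange(res.abs_dri.shape[1]) / res.frame_rate
            eff = (times >= 0.45) & (times < 0.6)
            means.append(np.nanmean(res.abs_dri[:, eff]))
        assert means[1] >= means[0]


class TestSensitivityToThreshold:
    @pytest.mark.parametrize("threshold", [1.0, 1.5, 2.25])
    def test_selection_monotone_in_threshold(self, sim_epochs, sim_dataset, threshold):
        """Selected sets shrink as the threshold rises but stay non-empty for
        planted contrasts in the studied range."""
        trials = sim_dataset["trials"]
        sel = select_electrodes(sim_epochs, trials, "wp0", threshold)
        assert len(sel.selected) > 0
        loose = select_electrodes(sim_epochs, trials, "wp0", 1.0)
        assert set(sel.selected) <= set(loose.selected)
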