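"""Time-resolved percept classification: calibration under the null, planted
separability, temporal generalization, weight localization with an ANOVA oracle."""

import warnings

import numpy as np
import pandas as pd
import pytest

from phonrestore.classify import (
    ClassifierTimecourse,
    classify_timecourse,
    temporal_generalization,
    weight_localization,
)
from conftest import synthetic_epochs


class TestClassifyTimecourse:
    def test_null_accuracy_within_chance_band(self):
        ep, trials = synthetic_epochs(n_e=4, n_f=200, n_per_cell=10,
                                      rng=np.random.default_rng(0))
        tc = classify_timecourse(ep, trials, "noise")
        n = tc.n_trials
        se = np.sqrt(0.25 / n)
        assert abs(np.nanmean(tc.accuracy) - 0.5) < 3 * se

    def test_planted_offset_perfectly_classified(self):
        ep, trials = synthetic_epochs(n_e=4, n_f=80, n_per_cell=5,
                                      rng=np.random.default_rng(1))
        cond = trials["condition"].to_numpy()
        perc = trials["reported_percept"].to_numpy()
        k = 40
        idx = np.flatnonzero((cond == "noise") & (perc == 1))
        ep.data[np.ix_(range(4), range(k, 80), idx)] += 10.0
        tc = classify_timecourse(ep, trials, "noise")
        half = int(round(0.110 * ep.frame_rate / 2))
        assert np.all(tc.accuracy[k + half :] == 1.0)
        assert tc.weights.min() >= 0

    def test_original_condition_uses_stimulus_labels(self):
        ep, trials = synthetic_epochs(n_e=3, n_f=60, n_per_cell=4,
                                      rng=np.random.default_rng(2))
        cond = trials["condition"].to_numpy()
        ep.data[np.ix_(range(3), range(60), np.flatnonzero(cond == "orig1"))] += 10.0
        tc = classify_timecourse(ep, trials, "original")
        assert np.all(tc.accuracy[~np.isnan(tc.accuracy)] == 1.0)

    def test_single_trial_class_rejected(self):
        ep, trials = synthetic_epochs(n_e=3, rng=np.random.default_rng(3))
        keep = ~((trials.condition == "noise") & (trials.reported_percept == 2))
        keep[trials.index[(trials.condition == "noise")
                          & (trials.reported_percept == 2)][0]] = True
        ep.data = ep.data[:, :, keep.to_numpy()]
        trials = trials[keep].reset_index(drop=True)
        with pytest.raises(ValueError, match=">=2 trials"):
            classify_timecourse(ep, trials, "noise")

    def test_trial_order_invariance(self):
        ep, trials = synthetic_epochs(n_e=3, n_f=30, n_per_cell=4,
                                      rng=np.random.default_rng(4))
        tc = classify_timecourse(ep, trials, "noise", time_range=(-0.4, -0.2))
        perm = np.random.default_rng(5).permutation(len(trials))
        ep2, _ = synthetic_epochs(n_e=3, n_f=30, n_per_cell=4,
                                  rng=np.random.default_rng(4))
        ep2.data = ep2.data[:, :, perm]
        trials2 = trials.iloc[perm].reset_index(drop=True)
        tc2 = classify_timecourse(ep2, trials2, "noise", time_range=(-0.4, -0.2))
        np.testing.assert_allclose(tc.accuracy, tc2.accuracy, equal_nan=True)

    def test_feature_scaling_leaves_separable_predictions(self):
        ep, trials = synthetic_epochs(n_e=3, n_f=30, n_per_cell=4,
                                      rng=np.random.default_rng(6))
        cond = trials["condition"].to_numpy()
        perc = trials["reported_percept"].to_numpy()
        idx = np.flatnonzero((cond == "noise") & (perc == 1))
        ep.data[np.ix_(range(3), range(30), idx)] += 10.0
        tc = classify_timecourse(ep, trials, "noise", time_range=(-0.45, -0.3))
        ep.data *= 5.0
        tc_scaled = classify_timecourse(ep, trials, "noise", time_range=(-0.45, -0.3))
        np.testing.assert_allclose(tc.accuracy, tc_scaled.accuracy, equal_nan=True)


class TestTemporalGeneralization:
    def test_self_consistency_at_train_frame(self):
        ep, trials = synthetic_epochs(n_e=3, n_f=60, n_per_cell=5,
                                      rng=np.random.default_rng(7))
        cond = trials["condition"].to_numpy()
        perc = trials["reported_percept"].to_numpy()
        idx = np.flatnonzero((cond == "noise") & (perc == 1))
        ep.data[np.ix_(range(3), range(20, 60), idx)] += 3.0
        center = 40
        acc = temporal_generalization(ep, trials, "noise", center)
        tc = classify_timecourse(ep, trials, "noise")
        assert acc[center] == tc.accuracy[center]

    def test_stationary_code_generalizes_flat(self):
        ep, trials = synthetic_epochs(n_e=3, n_f=60, n_per_cell=5,
                                      rng=np.random.default_rng(8))
        cond = trials["condition"].to_numpy()
        perc = trials["reported_percept"].to_numpy()
        idx = np.flatnonzero((cond == "noise") & (perc == 1))
        ep.data[np.ix_(range(3), range(60), idx)] += 10.0  # stationary offset
        acc = temporal_generalization(ep, trials, "noise", 30)
        valid = ~np.isnan(acc)
        assert np.all(acc[valid] == 1.0)

    def test_null_generalization_within_chance(self):
        ep, trials = synthetic_epochs(n_e=3, n_f=80, n_per_cell=10,
                                      rng=np.random.default_rng(9))
        acc = temporal_generalization(ep, trials, "noise", 40)
        n = 2 * 2 * 10
        valid = acc[~np.isnan(acc)]
        assert abs(valid.mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_train_window_outside_epoch_rejected(self):
        ep, trials = synthetic_epochs(n_e=3, n_f=40, rng=np.random.default_rng(10))
        with pytest.raises(ValueError, match="train window"):
            temporal_generalization(ep, trials, "noise", 2)


def _toy_timecourses(weights_by_cell, n_frames=60, frame_rate=100.0, t0=-0.3):
    """Build ClassifierTimecourse pairs whose window means are exactly the
    requested 2x2x2 cell values (hemisphere x location x condition)."""
    ids, rows = [], []
    n_per_cell = len(next(iter(weights_by_cell.values()))["original"])
    e = 0
    meta = []
    for (hemi, loc), conds in weights_by_cell.items():
        region = "IFG" if loc == "supra" else "STG"
        for i in range(n_per_cell):
            ids.append(f"e{e:03d}")
            meta.append({"id": f"e{e:03d}", "x_mm": 0.0, "y_mm": 0.0,
                         "region": region, "hemisphere": hemi})
            e += 1
    table = pd.DataFrame(meta)
    tcs = {}
    for cond in ("original", "noise"):
        w = np.zeros((e, n_frames))
        r = 0
        for (hemi, loc), conds in weights_by_cell.items():
            for val in conds[cond]:
                w[r, :] = val
                r += 1
        tcs[cond] = ClassifierTimecourse(
            condition_set=cond,
            accuracy=np.full(n_frames, 0.5),
            weights=w,
            times=t0 + np.arange(n_frames) / frame_rate,
            frames=np.arange(n_frames),
            n_trials=10,
            window_len=0.110,
            channel_ids=ids,
        )
    return tcs, table


def closed_form_three_way_anova(y, a, b, c):
    """Textbook balanced three-way fixed-effects ANOVA from cell means."""
    y, a, b, c = map(np.asarray, (y, a, b, c))
    n = len(y)
    gm = y.mean()
    levels = lambda f: np.unique(f)
    ss = {}
    mean_where = lambda mask: y[mask].mean()
    # main effects
    for name, f in (("A", a), ("B", b), ("C", c)):
        ss[name] = sum(
            (y[f == lv].size) * (mean_where(f == lv) - gm) ** 2 for lv in levels(f)
        )
    # two-way interactions
    for name, f, g, m1, m2 in (
        ("AB", a, b, "A", "B"), ("AC", a, c, "A", "C"), ("BC", b, c, "B", "C"),
    ):
        tot = 0.0
        for lv1 in levels(f):
            for lv2 in levels(g):
                mask = (f == lv1) & (g == lv2)
                tot += mask.sum() * (mean_where(mask) - gm) ** 2
        ss[name] = tot - ss[m1] - ss[m2]
    # three-way interaction
    tot = 0.0
    for l1 in levels(a):
        for l2 in levels(b):
            for l3 in levels(c):
                mask = (a == l1) & (b == l2) & (c == l3)
                tot += mask.sum() * (mean_where(mask) - gm) ** 2
    ss["ABC"] = tot - sum(ss[k] for k in ("A", "B", "C", "AB", "AC", "BC"))
    cell_count = len(levels(a)) * len(levels(b)) * len(levels(c))
    df_err = n - cell_count
    ss_err = sum(
        ((y[(a == l1) & (b == l2) & (c == l3)]
          - mean_where((a == l1) & (b == l2) & (c == l3))) ** 2).sum()
        for l1 in levels(a) for l2 in levels(b) for l3 in levels(c)
    )
    ms_err = ss_err / df_err
    return {k: (ss[k] / 1.0) / ms_err for k in ss}  # all factors have 1 df here


class TestWeightLocalization:
    def _cells(self, rng, shift=0.0):
        cells = {}
        for hemi in ("L", "R"):
            for loc in ("supra", "sub"):
                base = rng.normal(1.0, 0.2, 5)
                cells[(hemi, loc)] = {
                    "original": base + rng.normal(0, 0.05, 5),
                    "noise": base + shift * (hemi == "L") * (loc == "supra")
                    + rng.normal(0, 0.05, 5),
                }
        return cells

    def test_anova_matches_closed_form_on_balanced_table(self):
        rng = np.random.default_rng(0)
        tcs, table = _toy_timecourses(self._cells(rng, shift=0.6))
        stats = weight_localization(tcs["original"], tcs["noise"], table,
                                    cp_onset=0.0, pre=(-0.3, 0.0), post=(0.0, 0.3))
        sub = stats.table[stats.table.window == "pre"]
        f_hand = closed_form_three_way_anova(
            sub["weight"].to_numpy(),
            sub["hemisphere"].to_numpy(),
            sub["location"].to_numpy(),
            sub["condition"].to_numpy(),
        )
        an = stats.anova["pre"]
        mapping = {
            "A": "C(hemisphere)",
            "B": "C(location)",
            "C": "C(condition)",
            "AB": "C(hemisphere):C(location)",
            "AC": "C(hemisphere):C(condition)",
            "BC": "C(location):C(condition)",
            "ABC": "C(hemisphere):C(location):C(condition)",
        }
        for k, row in mapping.items():
            assert an.loc[row, "F"] == pytest.approx(f_hand[k], abs=1e-9)

    def test_identical_weights_give_zero_f(self):
        cells = {
            (h, l): {"original": [1.0] * 4, "noise": [1.0] * 4}
            for h in ("L", "R") for l in ("supra", "sub")
        }
        tcs, table = _toy_timecourses(cells)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stats = weight_localization(tcs["original"], tcs["noise"], table,
                                        cp_onset=0.0)
        for an in stats.anova.values():
            f = an["F"].dropna()
            assert np.allclose(f, 0.0, atol=1e-8)
        if len(stats.posthoc):
            assert np.allclose(stats.posthoc["t"], 0.0, atol=1e-8)

    def test_bonferroni_adjustment_inflates_p(self):
        rng = np.random.default_rng(1)
        tcs, table = _toy_timecourses(self._cells(rng, shift=0.3))
        stats = weight_localization(tcs["original"], tcs["noise"], table,
                                    cp_onset=0.0)
        assert (stats.posthoc["p_bonf"] >= stats.posthoc["p_raw"] - 1e-12).all()

    def test_single_level_factor_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        cells = {k: v for k, v in self._cells(rng).items() if k[0] == "L"}
        tcs, table = _toy_timecourses(cells)
        with pytest.warns(UserWarning, match="hemisphere"):
            stats = weight_localization(tcs["original"], tcs["noise"], table,
                                        cp_onset=0.0)
        for an in stats.anova.values():
            assert not any("hemisphere" in ix for ix in an.index)
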