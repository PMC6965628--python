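"""Trial selection rules and cluster-based permutation testing."""

import numpy as np
import pandas as pd
import pytest

from netlag.behavior import TrialTable
from netlag.localize import (ClusterResult, EpochSet,
                             cluster_permutation_test, epoch, screen_network,
                             select_trials)


def make_table(categories, outcomes):
    n = len(categories)
    rts = np.where([o in ("correct_commission", "commission_error")
                    for o in outcomes], 0.5, np.nan)
    return TrialTable(onsets=np.arange(n) * 0.8,
                      categories=np.asarray(categories, dtype=object),
                      rts=rts, outcomes=np.asarray(outcomes, dtype=object))


class TestSelectTrials:
    def test_toy_sequence_counts(self):
        cats = ["city", "city", "city", "mountain", "city", "city", "city"]
        outs = ["correct_commission"] * 3 + ["correct_omission"] + \
               ["correct_commission"] * 3
        sel = select_trials(make_table(cats, outs), seed=0)
        assert list(sel.targets) == [3]
        # interior cities flanked by correct cities: trials 1 and 5
        assert list(sel.baselines_all) == [1, 5]
        assert len(sel.baselines) == 1

    def test_mountain_after_mountain_excluded(self):
        cats = ["city", "mountain", "mountain", "city"]
        outs = ["correct_commission", "correct_omission", "correct_omission",
                "correct_commission"]
        sel = select_trials(make_table(cats, outs), seed=0)
        assert list(sel.targets) == [1]

    def test_commission_error_targets_reported_separately(self):
        cats = ["city", "mountain", "city", "mountain", "city"]
        outs = ["correct_commission", "commission_error", "correct_commission",
                "correct_omission", "correct_commission"]
        sel = select_trials(make_table(cats, outs), seed=0)
        assert list(sel.targets) == [3]
        assert list(sel.targets_error) == [1]

    def test_city_next_to_omission_error_ineligible(self):
        cats = ["city"] * 5 + ["mountain"] + ["city"]
        outs = ["correct_commission", "correct_commission", "omission_error",
                "correct_commission", "correct_commission",
                "correct_omission", "correct_commission"]
        sel = select_trials(make_table(cats, outs), seed=0)
        # trial 1 and 3 flank the omission error at 2; trial 4 flanks mountain
        assert 1 not in sel.baselines_all
        assert 3 not in sel.baselines_all

    def test_subsampling_is_seeded(self):
        cats = ["city"] * 20 + ["mountain"]
        outs = ["correct_commission"] * 20 + ["correct_omission"]
        t = make_table(cats, outs)
        a = select_trials(t, seed=5).baselines
        b = select_trials(t, seed=5).baselines
        c = select_trials(t, seed=6).baselines
        assert np.array_equal(a, b)
        assert len(a) == len(c) == 1

    def test_no_targets_is_an_error(self):
        cats = ["city", "mountain", "city"]
        outs = ["correct_commission", "commission_error", "correct_commission"]
        with pytest.raises(ValueError):
            select_trials(make_table(cats, outs), seed=0)


class TestEpoch:
    def test_sample_count_and_indexing(self):
        fs = 1000.0
        env = np.zeros(int(10 * fs))
        env[int(3.0 * fs + 0.5 * fs)] = 1.0       # impulse 500 ms after onset 3 s
        es = epoch(env, fs, np.array([3.0]), (-800.0, 1600.0))
        assert es.data.shape == (1, 2400)
        peak_ms = es.times_ms[np.argmax(es.data[0])]
        assert peak_ms == pytest.approx(500.0, abs=1.0)

    def test_constant_envelope(self):
        es = epoch(np.full(5000, 2.2), 1000.0, np.array([1.0, 2.0]))
        assert np.allclose(es.data, 2.2)

    def test_out_of_range_trials_dropped(self):
        es = epoch(np.zeros(3000), 1000.0, np.array([0.1, 1.2, 2.9]))
        assert es.n_trials == 1
        assert list(es.dropped_trials) == [0, 2]

    def test_edge_flagged_samples_drop_trials(self):
        valid = np.ones(5000, dtype=bool)
        valid[:1500] = False
        es = epoch(np.zeros(5000), 1000.0, np.array([1.0, 3.0]), valid=valid)
        assert list(es.dropped_trials) == [0]


def _epochs(data, fs=100.0, t0=-800.0, label=""):
    n_t = data.shape[1]
    times = t0 + np.arange(n_t) / fs * 1000.0
    return EpochSet(data=data, times_ms=times, fs=fs, label=label)


class TestClusterPermutation:
    def test_injected_effect_detected_with_correct_sign_and_window(self):
        rng = np.random.default_rng(0)
        fs = 100.0
        x = rng.standard_normal((50, 240))
        y = rng.standard_normal((50, 240))
        tsel = slice(120, 170)        # 400..900 ms post-onset at 100 Hz
        x[:, tsel] += 2.0
        res = cluster_permutation_test(_epochs(x, fs), _epochs(y, fs),
                                       n_perm=500, seed=1)
        assert res.responsive and res.sign == +1
        win = max(res.clusters, key=lambda c: abs(c.mass))
        assert win.start_ms < 900 and win.end_ms > 400

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((40, 240))
        y = rng.standard_normal((40, 240))
        x[:, 130:160] += 1.5
        a = cluster_permutation_test(_epochs(x), _epochs(y), n_perm=400, seed=3)
        b = cluster_permutation_test(_epochs(y), _epochs(x), n_perm=400, seed=3)
        assert a.sign == -b.sign
        assert a.max_mass == pytest.approx(-b.max_mass)
        assert a.p == pytest.approx(b.p, abs=0.02)   # Monte-Carlo resolution

    def test_mass_invariant_to_common_offset(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((30, 240))
        y = rng.standard_normal((30, 240))
        x[:, 100:140] += 1.0
        a = cluster_permutation_test(_epochs(x), _epochs(y), n_perm=100, seed=5)
        b = cluster_permutation_test(_epochs(x + 3.0), _epochs(y + 3.0),
                                     n_perm=100, seed=5)
        assert a.max_mass == pytest.approx(b.max_mass)
        assert a.p == b.p

    def test_null_p_superuniform_small(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(60):
            x = rng.standard_normal((20, 120))
            y = rng.standard_normal((20, 120))
            res = cluster_permutation_test(_epochs(x, 100.0), _epochs(y, 100.0),
                                           n_perm=200,
                                           seed=int(rng.integers(2 ** 31)))
            ps.append(res.p)
        # rejection at alpha=0.2 should not exceed 0.2 by much
        assert np.mean(np.asarray(ps) < 0.2) < 0.35

    def test_degenerate_inputs_rejected(self):
        x = np.zeros((1, 240))
        with pytest.raises(ValueError):
            cluster_permutation_test(_epochs(x), _epochs(x))
        with pytest.raises(ValueError):
            cluster_permutation_test(_epochs(np.zeros((5, 240))),
                                     _epochs(np.zeros((5, 240))), n_perm=0)


class TestScreenNetwork:
    def _table(self):
        return pd.DataFrame({
            "channel": ["a", "b", "c", "d"],
            "subject": ["s1", "s1", "s1", "s2"],
            "network": ["DAN", "DAN", "DMN", "SN"],
        })

    def _res(self, ch, p, sign):
        return ClusterResult(channel=ch, clusters=[], max_mass=3.0 * sign,
                             p=p, responsive=p < 0.05, sign=sign)

    def test_sign_matching_and_correction(self):
        results = [self._res("a", 0.01, +1), self._res("b", 0.04, +1),
                   self._res("c", 0.01, +1), self._res("d", 0.01, -1)]
        out = screen_network(results, self._table()).set_index("channel")
        assert out.loc["a", "retained"]              # 0.01 * 2 < 0.05
        assert not out.loc["b", "retained"]          # 0.04 * 2 > 0.05
        # DMN site with positive cluster is opposite-sign, not retained
        assert not out.loc["c", "retained"] and out.loc["c", "opposite_sign"]
        # SN site with negative cluster likewise
        assert not out.loc["d", "retained"] and out.loc["d", "opposite_sign"]

    def test_single_electrode_network_correction_is_identity(self):
        out = screen_network([self._res("d", 0.03, +1)], self._table())
        assert out.iloc[0]["p_corrected"] == pytest.approx(0.03)
        assert out.iloc[0]["retained"]

    def test_unlabeled_channels_excluded(self):
        table = pd.DataFrame({"channel": ["x"], "subject": ["s1"],
                              "network": ["none"]})
        out = screen_network([self._res("x", 0.001, +1)], table)
        assert len(out) == 0
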