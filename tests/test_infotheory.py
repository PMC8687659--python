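"""Plug-in entropy and transfer-entropy estimators against closed forms."""

import numpy as np
import pytest

from infoflow.encoding import RotationSeries
from infoflow.errors import ConfigurationError, DataError
from infoflow.infotheory import (TransferEntropyModel, conditional_entropy,
                                 local_te_by_distance, local_transfer_entropy,
                                 marginal_entropy, net_predictive_power,
                                 pair_te, parameter_scan, transfer_entropy)
from infoflow.simulate import generate_binary_channel


def series(symbols):
    return RotationSeries(symbols=np.asarray(symbols, dtype=np.int8),
                          sampling_period=0.2)


def brute_force_channel_te(p):
    """Exact TE over the analytic channel's joint distribution (k=1)."""
    te = 0.0
    P = {}
    for s in (0, 1):
        for t in (0, 1):
            for t1 in (0, 1):
                P[(t1, t, s)] = 0.25 * ((1 - p) if t1 == s else p)
    for (t1, t, s), pr in P.items():
        if pr == 0:
            continue
        p_n_hs = pr / sum(P[(a, t, s)] for a in (0, 1))
        p_n_h = (sum(P[(t1, t, b)] for b in (0, 1)) /
                 sum(P[(a, t, b)] for a in (0, 1) for b in (0, 1)))
        te += pr * np.log2(p_n_hs / p_n_h)
    return te


class TestEntropies:
    def test_constant_series_zero_bits(self):
        assert marginal_entropy(series([0] * 100)) == 0.0

    def test_balanced_series_one_bit(self):
        assert marginal_entropy(series([0, 1] * 50)) == pytest.approx(1.0)

    def test_quarter_three_quarter_closed_form(self):
        s = series([0] * 25 + [1] * 75)
        assert marginal_entropy(s) == pytest.approx(0.811278, abs=1e-5)

    def test_empty_raises(self):
        with pytest.raises(DataError):
            marginal_entropy(series([]))

    def test_alternating_series_fully_predicted(self):
        assert conditional_entropy(series([0, 1] * 200), k=1) == pytest.approx(0.0)

    def test_iid_fair_series_about_one_bit(self):
        rng = np.random.default_rng(1)
        s = series(rng.integers(0, 2, 20000))
        assert conditional_entropy(s, k=1) == pytest.approx(1.0, abs=0.01)

    def test_period_four_pattern_k2_deterministic(self):
        # 0011 repeated: every 2-symbol context determines the next symbol
        assert conditional_entropy(series([0, 0, 1, 1] * 100), k=2) == pytest.approx(0.0)

    def test_k_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            conditional_entropy(series([0, 1] * 50), k=0)


class TestTransferEntropy:
    @pytest.mark.parametrize("p_flip", [0.0, 0.1, 0.25, 0.5])
    def test_channel_matches_brute_force_closed_form(self, p_flip):
        src, tgt = generate_binary_channel(100_000, p_flip, seed=42)
        res = transfer_entropy(src, tgt, k=1)
        assert res.te_bits == pytest.approx(brute_force_channel_te(p_flip), abs=0.01)

    def test_reverse_direction_carries_nothing(self):
        src, tgt = generate_binary_channel(100_000, 0.1, seed=7)
        assert transfer_entropy(tgt, src, k=1).te_bits < 0.001

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(3)
        a = series(rng.integers(0, 2, 100_000))
        b = series(rng.integers(0, 2, 100_000))
        assert transfer_entropy(a, b, k=1).te_bits < 0.001

    def test_te_bounded_by_conditional_entropy(self, coupled_colony):
        for pf in coupled_colony[:3]:
            res_en, res_ne = pair_te(pf, k=10)
            for r in (res_en, res_ne):
                assert 0.0 <= r.te_bits <= r.h_cond_bits <= 1.0 + 1e-12
                assert 0.0 <= r.predictive_power_pct <= 100.0

    def test_invariant_under_global_relabelling(self):
        src, tgt = generate_binary_channel(20_000, 0.2, seed=5)
        te1 = transfer_entropy(src, tgt, k=2).te_bits
        flipped_src = series(1 - src.symbols)
        flipped_tgt = series(1 - tgt.symbols)
        te2 = transfer_entropy(flipped_src, flipped_tgt, k=2).te_bits
        assert te1 == pytest.approx(te2, abs=1e-12)

    def test_plugin_error_shrinks_as_root_n(self):
        errs = []
        for n in (10 ** 3, 10 ** 4, 10 ** 5):
            vals = [abs(transfer_entropy(*generate_binary_channel(n, 0.1, seed=s),
                                         k=1).te_bits - brute_force_channel_te(0.1))
                    for s in range(5)]
            errs.append(np.mean(vals))
        assert errs[0] > errs[2]
        assert all(e < 3.0 / np.sqrt(n) for e, n in zip(errs, (1e3, 1e4, 1e5)))

    def test_length_mismatch_raises(self):
        with pytest.raises(DataError):
            transfer_entropy(series([0, 1] * 10), series([0, 1] * 11), k=1)

    def test_summary_renders(self):
        src, tgt = generate_binary_channel(5000, 0.1, seed=0)
        text = TransferEntropyModel(src, tgt, k=1).fit().summary()
        assert "transfer entropy" in text and "predictive power" in text


class TestLocalTransferEntropy:
    def test_mean_equals_te_exactly(self):
        src, tgt = generate_binary_channel(50_000, 0.15, seed=9)
        res = TransferEntropyModel(src, tgt, k=3).fit()
        assert abs(res.local.mean() - res.te_bits) < 1e-9

    def test_deterministic_copy_every_value_one_bit(self):
        # every counted transition is maximally informative; the plug-in
        # probabilities wobble around 1/2 by the empirical symbol frequency
        src, tgt = generate_binary_channel(10_000, 0.0, seed=2)
        loc = local_transfer_entropy(src, tgt, k=1)
        assert np.all(loc.values > 0.9)
        assert np.mean(loc.values) == pytest.approx(1.0, abs=0.01)

    def test_independent_series_both_signs_mean_zero(self):
        rng = np.random.default_rng(11)
        a = series(rng.integers(0, 2, 50_000))
        b = series(rng.integers(0, 2, 50_000))
        loc = local_transfer_entropy(a, b, k=1)
        assert (loc.values > 0).any() and (loc.values < 0).any()
        assert abs(loc.mean()) < 0.001


class TestPredictivePower:
    def test_symmetric_inputs_zero_net(self):
        src, tgt = generate_binary_channel(10_000, 0.1, seed=1)
        r1 = transfer_entropy(src, src, k=1)
        assert net_predictive_power(r1, r1) == 0.0

    def test_strong_channel_positive_net_and_antisymmetric(self):
        src, tgt = generate_binary_channel(50_000, 0.05, seed=4)
        r_en = transfer_entropy(src, tgt, k=1)
        r_ne = transfer_entropy(tgt, src, k=1)
        net = net_predictive_power(r_en, r_ne)
        assert net > 0
        assert net_predictive_power(r_ne, r_en) == pytest.approx(-net)

    def test_settings_mismatch_rejected(self):
        src, tgt = generate_binary_channel(10_000, 0.1, seed=1)
        r1 = transfer_entropy(src, tgt, k=1)
        r2 = transfer_entropy(tgt, src, k=2)
        with pytest.raises(ConfigurationError):
            net_predictive_power(r1, r2)


class TestParameterScan:
    def test_single_k_grid_has_argmax(self, coupled_colony):
        scan = parameter_scan(coupled_colony[:3], periods=[0.2, 1.0], ks=[1])
        assert len(scan.grid) == 2
        assert scan.best_k == 1 and scan.best_period in (0.2, 1.0)

    def test_total_te_decays_with_period_for_fast_coupling(self):
        # tightly coupled pairs exchange information at the sample scale, so
        # coarser symbolisation drains the measurable transfer towards zero;
        # long flights keep the small-sample plug-in bias off the 4 s cell
        from infoflow.simulate import SimConfig, simulate_pair_flight
        pairs = []
        for seed in range(3):
            cfg = SimConfig(n_steps=8000, w_couple=0.85, alpha_attract=0.1,
                            sigma_heading=0.3, beta_home=0.05, q_switch=0.0,
                            home=(100000.0, 0.0), seed=700 + seed)
            pairs.append(simulate_pair_flight(cfg, metadata=(f"p{seed}", 2, 1))[0])
        scan = parameter_scan(pairs, periods=[0.2, 1.0, 4.0], ks=[2])
        g = scan.grid.set_index("period")["mean_total_te_bits"]
        assert g[0.2] > g[1.0] > g[4.0]
        assert g[4.0] < 0.05          # at the small-sample bias floor
        assert scan.best_period == 0.2


class TestLocalTEByDistance:
    def test_single_bin_mean_matches_global_mean(self, coupled_colony):
        pf = coupled_colony[0]
        table = local_te_by_distance([pf], k=5, bins=[-1e6, 1e6], n_boot=10)
        res_en, _ = pair_te(pf, k=5, store_local=True)
        row = table[table.direction == "EN"].iloc[0]
        # the single bin holds every transition with valid d_EN
        assert row.mean_local_te_bits == pytest.approx(
            np.mean(res_en.local.values[
                np.isfinite(res_en.local.values)]), abs=0.02)

    def test_front_bird_dominates_within_30m(self, coupled_colony):
        table = local_te_by_distance(coupled_colony, k=10,
                                     bins=np.arange(-30, 31, 10.0),
                                     n_boot=50, seed=1)
        bins = (table.dropna(subset=["front_dominance_bits"])
                .groupby("bin_left")
                .agg(dom=("front_dominance_bits", "first"),
                     n=("n_transitions", "first")))
        # bins below 1% of transitions cannot resolve the direction contrast
        populated = bins[bins.n >= 0.01 * bins.n.sum()]
        assert len(populated) >= 3
        assert (populated.dom > 0).all()
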