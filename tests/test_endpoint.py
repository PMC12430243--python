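"""Curve assembly, smoothing and endpoint detection."""

import numpy as np
import pytest

from titracam import (
    NoSignalError,
    NoTransitionError,
    PROFILES,
    SimulationConfig,
    detect_endpoint,
    extract_channel,
    rank_channels,
    simulate_curve,
    smooth,
)

from conftest import make_curve


class TestExtractChannel:
    def test_constant_curve_gives_constant_series(self):
        curve = make_curve(np.arange(6) * 0.02, [(206, 223, 89)] * 6)
        vols, sig = extract_channel(curve, "G")
        assert np.all(sig == 223.0)
        assert len(vols) == 6

    def test_hue_unwrap_across_the_red_boundary(self):
        # ~356 deg -> ~5 deg is a small step through the red wrap, not -351
        curve = make_curve([0.0, 0.02], [(250, 55, 72), (250, 89, 72)])
        _, hues = extract_channel(curve, "Hue")
        assert 350.0 < hues[0] < 360.0
        assert hues[1] > 360.0  # unwrapped past the boundary
        assert abs(hues[1] - hues[0]) < 20.0

    def test_hnb_anchored_curve_descends_in_hue(self):
        sim = simulate_curve(
            PROFILES["hnb_water"],
            SimulationConfig(ca_amount=50, noise_sd=0, quantize=False),
        )
        _, hues = extract_channel(sim.curve, "Hue")
        assert hues[0] == pytest.approx(301.8, abs=0.1)
        assert hues[-1] == pytest.approx(231.8, abs=0.1)

    def test_achromatic_points_forward_filled_and_leading_dropped(self):
        rows = [(128, 128, 128), (100, 50, 50), (90, 90, 90), (50, 50, 100)]
        curve = make_curve([0.0, 0.02, 0.04, 0.06], rows)
        vols, hues = extract_channel(curve, "Hue")
        assert len(vols) == 3 and vols[0] == 0.02
        assert hues[1] == hues[0]  # carried forward over the gray point

    def test_all_achromatic_is_no_signal(self):
        curve = make_curve([0.0, 0.02], [(5, 5, 5), (7, 7, 7)])
        with pytest.raises(NoSignalError):
            extract_channel(curve, "Hue")


class TestSmooth:
    def test_window_one_is_identity(self):
        series = [3.0, 1.0, 4.0, 1.0, 5.0]
        assert np.array_equal(smooth(series, 1), series)

    def test_constant_series_unchanged(self):
        assert np.all(smooth([7.0] * 9, 5) == 7.0)

    def test_spike_spread_with_shrinking_end_windows(self):
        out = smooth([0, 0, 10, 0, 0], 3)
        assert out == pytest.approx([0.0, 10 / 3, 10 / 3, 10 / 3, 0.0])

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError):
            smooth([1.0, 2.0, 3.0, 4.0, 5.0], window)


class TestDetectEndpoint:
    def test_ideal_step_midpoint_by_max_slope(self, step_curve):
        res = detect_endpoint(step_curve, "R", "max_slope", smooth_window=1)
        assert res.v_endpoint == pytest.approx(2.01, abs=1e-9)
        assert res.jump == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize("method", ["sigmoid", "max_slope"])
    def test_noiseless_logistic_recovery(self, method):
        # logistic transition centered at 1.25 mL with k = 40 /mL
        vols = np.round(np.arange(0, 3.001, 0.02), 4)
        sig = 200.0 - 100.0 / (1.0 + np.exp(-40.0 * (vols - 1.25)))
        curve = make_curve(vols, [(s, 40, 40) for s in sig], increment=0.02)
        res = detect_endpoint(curve, "R", method)
        assert res.v_endpoint == pytest.approx(1.25, abs=0.02)

    def test_constant_signal_raises_no_transition(self):
        curve = make_curve(np.arange(10) * 0.02, [(100, 100, 40)] * 10)
        with pytest.raises(NoTransitionError):
            detect_endpoint(curve, "R", "max_slope")

    def test_small_jump_buried_in_noise_rejected(self):
        rng = np.random.default_rng(11)
        vols = np.round(np.arange(0, 4.001, 0.02), 4)
        sig = 100.0 + 2.0 * (vols > 2.0) + rng.normal(0, 3.0, vols.size)
        sig = np.clip(sig, 0, 255)
        curve = make_curve(vols, [(s, 40, 40) for s in sig], increment=0.02)
        with pytest.raises(NoTransitionError):
            detect_endpoint(curve, "R", "max_slope")

    def test_rising_and_falling_handled_identically(self):
        vols = np.round(np.arange(0, 3.001, 0.02), 4)
        sig = 100.0 + 80.0 / (1.0 + np.exp(-40.0 * (vols - 1.4)))
        up = make_curve(vols, [(s, 40, 40) for s in sig], increment=0.02)
        down = make_curve(vols, [(200 - s, 40, 40) for s in sig], increment=0.02)
        r_up = detect_endpoint(up, "R", "sigmoid")
        r_down = detect_endpoint(down, "R", "sigmoid")
        assert r_up.v_endpoint == pytest.approx(r_down.v_endpoint, abs=1e-6)
        assert r_up.jump == pytest.approx(r_down.jump, abs=1e-6)

    def test_max_slope_tie_broken_to_smallest_volume(self):
        # two equal unit drops: the earlier one must win (under-titration bias)
        vols = np.round(np.arange(0, 0.2, 0.02), 4)
        sig = [100, 100, 100, 50, 50, 50, 0, 0, 0, 0]
        curve = make_curve(vols, [(s, 10, 10) for s in sig], increment=0.02)
        res = detect_endpoint(curve, "R", "max_slope", smooth_window=1)
        assert res.v_endpoint == pytest.approx(0.05)

    def test_too_few_points_rejected(self):
        curve = make_curve([0.0, 0.02, 0.04], [(1, 2, 3)] * 3)
        with pytest.raises(ValueError, match="at least 5"):
            detect_endpoint(curve, "R")

    @pytest.mark.parametrize("channel", ["R", "G", "B", "Hue"])
    @pytest.mark.parametrize("method", ["sigmoid", "max_slope"])
    def test_noiseless_simulated_recovery_all_chromatic_channels(self, channel, method):
        # calcein moves every channel monotonically (R by only 1 unit);
        # endpoint within one increment on each channel with a nonzero jump
        sim = simulate_curve(
            PROFILES["calcein_milk"],
            SimulationConfig(ca_amount=50, blank_volume=1.25, noise_sd=0),
        )
        res = detect_endpoint(sim.curve, channel, method)
        assert abs(res.v_endpoint - sim.true_endpoint) <= 0.02 + 1e-9

    def test_gain_robustness_of_hue_endpoint(self):
        base = SimulationConfig(ca_amount=50, blank_volume=1.25, noise_sd=1, seed=4)
        for gain in (0.6, 0.8, 1.2, 1.4):
            scaled = SimulationConfig(
                ca_amount=50, blank_volume=1.25, noise_sd=1, seed=4,
                gain_drift=(gain, gain),
            )
            r0 = detect_endpoint(simulate_curve(PROFILES["hnb_water"], base).curve, "Hue")
            r1 = detect_endpoint(simulate_curve(PROFILES["hnb_water"], scaled).curve, "Hue")
            assert abs(r0.v_endpoint - r1.v_endpoint) <= 0.02

    def test_refining_increment_moves_endpoint_at_most_coarse_step(self):
        for inc_coarse, inc_fine in [(0.05, 0.02)]:
            coarse = simulate_curve(
                PROFILES["hnb_water"],
                SimulationConfig(ca_amount=47, noise_sd=0, increment=inc_coarse),
            )
            fine = simulate_curve(
                PROFILES["hnb_water"],
                SimulationConfig(ca_amount=47, noise_sd=0, increment=inc_fine),
            )
            for method in ("sigmoid", "max_slope"):
                rc = detect_endpoint(coarse.curve, "Hue", method)
                rf = detect_endpoint(fine.curve, "Hue", method)
                assert abs(rc.v_endpoint - rf.v_endpoint) <= inc_coarse + 1e-9


class TestRankChannels:
    def test_calcein_milk_prefers_green_and_hue(self):
        sim = simulate_curve(
            PROFILES["calcein_milk"],
            SimulationConfig(ca_amount=50, blank_volume=1.25, noise_sd=1, seed=1),
        )
        ranking = rank_channels(sim.curve)
        order = ranking.order()
        # Red barely moves (206 -> 205); Green (55 units) and Hue must outrank it
        assert order.index("G") < order.index("R")
        assert order.index("Hue") < order.index("R")
        assert ranking.recommended == ("G", "Hue")

    def test_hnb_water_ranks_green_last(self):
        sim = simulate_curve(
            PROFILES["hnb_water"],
            SimulationConfig(ca_amount=50, blank_volume=1.25, noise_sd=1, seed=1),
        )
        ranking = rank_channels(sim.curve)
        assert ranking.order()[-1] == "G"  # Green anchors move only 2 units
        assert ranking.recommended == ("R", "Hue")

    def test_constant_curve_scores_all_zero(self):
        curve = make_curve(np.arange(8) * 0.02, [(100, 120, 140)] * 8)
        ranking = rank_channels(curve)
        assert all(s.score == 0.0 for s in ranking.scores)
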