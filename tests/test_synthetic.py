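"""Kinetic model, phantom sampling and series simulation."""

import math

import numpy as np
import pytest

from aslpower import (KineticParams, NoiseConfig, PhantomConfig,
                      get_protocol, kinetic_delta_m, sample_tissue_map,
                      simulate_series, split_and_subtract)
from aslpower.containers import GM, WM, CSF, MIXED
from aslpower.exceptions import InvalidParameterError


def reference_delta_m(cbf, delta, ld, pld, t1b, eps, lam, m0):
    """Independent scalar evaluation of the piecewise bolus model.

    Written from the closed form directly with math.* calls; shares no code
    with the package implementation.
    """
    t = ld + pld
    amp = 2.0 * eps * m0 * (cbf / lam) * (t1b / 60000.0)
    if t <= delta:
        return 0.0
    if t <= delta + ld:
        return amp * math.exp(-delta / t1b) * (1.0 - math.exp(-(t - delta) / t1b))
    return (amp * math.exp(-delta / t1b) * (1.0 - math.exp(-ld / t1b))
            * math.exp(-(t - delta - ld) / t1b))


class TestKineticDeltaM:
    def test_zero_flow_zero_signal(self, exp3):
        assert kinetic_delta_m(0.0, 1000.0, exp3) == 0.0

    def test_label_not_arrived(self, exp3):
        # transit >= LD + PLD = 3650 ms: nothing delivered at readout
        assert kinetic_delta_m(60.0, 3650.0, exp3) == 0.0
        assert kinetic_delta_m(60.0, 5000.0, exp3) == 0.0

    def test_matches_independent_oracle(self, exp3):
        kp = KineticParams(t1_blood=1650, labeling_efficiency=0.75,
                           bs_efficiency=1.0, blood_brain_partition=0.9,
                           equilibrium_magnetization=1.0)
        got = kinetic_delta_m(60.0, 1000.0, exp3, kp)
        want = reference_delta_m(60.0, 1000.0, 2150, 1500, 1650, 0.75, 0.9, 1.0)
        assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("delta", [0.0, 500.0, 1400.0, 2000.0, 3000.0])
    def test_matches_oracle_across_transit_times(self, exp3, delta):
        kp = KineticParams()
        want = reference_delta_m(
            20.0, delta, exp3.label_duration, exp3.post_label_delay,
            kp.t1_blood, kp.labeling_efficiency * kp.bs_efficiency,
            kp.blood_brain_partition, kp.equilibrium_magnetization)
        assert kinetic_delta_m(20.0, delta, exp3, kp) == pytest.approx(
            want, abs=1e-12)

    def test_continuity_at_breakpoints(self, exp3):
        """dM is continuous across both piecewise breakpoints.

        With readout fixed at t = LD + PLD, the branch switches happen at
        transit times delta = t - tau (end-of-bolus at readout) and
        delta = t (arrival at readout); straddling each by 1e-7 ms must
        change dM by less than 1e-9.
        """
        t = exp3.readout_time
        tau = exp3.label_duration
        eps_t = 1e-12
        for d_break in (t - tau, t):
            left = kinetic_delta_m(35.0, d_break - eps_t, exp3)
            right = kinetic_delta_m(35.0, d_break + eps_t, exp3)
            assert abs(left - right) < 1e-9

    def test_nonnegative_everywhere(self, exp3):
        deltas = np.linspace(0, 6000, 200)
        dm = kinetic_delta_m(np.full_like(deltas, 20.0), deltas, exp3)
        assert np.all(dm >= 0)

    def test_protocol_ranking_short_transit(self):
        """Longer labeling (exp3) beats longer delay (exp2) for ATT <= 1500 ms."""
        e2, e3 = get_protocol("exp2"), get_protocol("exp3")
        for delta in np.linspace(0, 1500, 31):
            assert (kinetic_delta_m(20.0, delta, e3)
                    >= kinetic_delta_m(20.0, delta, e2))

    def test_negative_inputs_rejected(self, exp3):
        with pytest.raises(InvalidParameterError):
            kinetic_delta_m(-1.0, 1000.0, exp3)
        with pytest.raises(InvalidParameterError):
            kinetic_delta_m(20.0, -5.0, exp3)


class TestSampleTissueMap:
    def test_deterministic_given_seed(self):
        a = sample_tissue_map(seed=11)
        b = sample_tissue_map(seed=11)
        assert np.array_equal(a.tissue_class, b.tissue_class)
        assert np.array_equal(a.cbf, b.cbf)
        assert np.array_equal(a.responder, b.responder)

    def test_all_layers_present(self, small_phantom):
        classes = set(np.unique(small_phantom.tissue_class))
        assert {0, GM, WM, CSF, MIXED} <= classes

    def test_nonresponder_count_exact(self):
        cfg = PhantomConfig(non_responder_fraction=0.1)
        tm = sample_tissue_map(config=cfg, seed=5)
        n_wm = tm.wm_mask.sum()
        n_nr = (~tm.responder).sum()
        assert n_nr == round(0.1 * n_wm)
        assert np.all(tm.responder[~tm.wm_mask])  # only WM voxels flagged

    def test_zero_fraction_all_respond(self):
        cfg = PhantomConfig(non_responder_fraction=0.0)
        tm = sample_tissue_map(config=cfg, seed=5)
        assert tm.responder.all()

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            PhantomConfig(non_responder_fraction=1.5)

    def test_wm_cbf_ratio_invariant(self):
        with pytest.raises(InvalidParameterError):
            PhantomConfig(gm_cbf_mean=60, wm_cbf_mean=50)  # > GM/2

    def test_wm_mean_within_monte_carlo_error(self):
        """Sampled WM CBF mean tracks the configured 20 mL/100g/min."""
        cfg = PhantomConfig(shape=(48, 48, 8))
        tm = sample_tissue_map(config=cfg, seed=3)
        wm_cbf = tm.cbf[tm.wm_mask]
        se = cfg.wm_cbf_sd / np.sqrt(wm_cbf.size)
        assert abs(wm_cbf.mean() - cfg.wm_cbf_mean) < 3 * se
        gm_mean = tm.cbf[tm.gm_mask].mean()
        assert gm_mean / 4 <= wm_cbf.mean() <= gm_mean / 2


class TestSimulateSeries:
    def test_noiseless_difference_equals_kinetic_model(self, exp3,
                                                       small_phantom):
        series, _ = simulate_series(small_phantom, exp3,
                                    noise=NoiseConfig(noise_sd=0.0), seed=1)
        diff = split_and_subtract(series)
        dm = kinetic_delta_m(small_phantom.cbf, small_phantom.transit_time,
                             exp3)
        resp = small_phantom.responder
        assert np.allclose(diff.data[resp],
                           np.asarray(dm)[resp][:, None], atol=1e-12)

    def test_nonresponder_noiseless_differences_nonpositive(self, exp3):
        cfg = PhantomConfig(shape=(16, 16, 8), non_responder_fraction=0.5)
        tm = sample_tissue_map(config=cfg, seed=2)
        series, _ = simulate_series(
            tm, exp3, noise=NoiseConfig(noise_sd=0.0, nonresponder_scale=5.0),
            seed=2)
        diff = split_and_subtract(series)
        nr = ~tm.responder
        assert np.all(diff.data[nr] <= 0)

    def test_difference_noise_sd(self, exp3):
        """Difference of two independent draws has sd sigma * sqrt(2)."""
        cfg = PhantomConfig(shape=(4, 4, 8))
        tm = sample_tissue_map(config=cfg, seed=3)
        sigma = 25.0
        proto = exp3.with_pairs(10000)
        series, _ = simulate_series(tm, proto,
                                    noise=NoiseConfig(noise_sd=sigma), seed=3)
        diff = split_and_subtract(series)
        voxel = np.argwhere(tm.wm_mask)[0]
        d = diff.data[tuple(voxel)]
        assert d.std(ddof=1) == pytest.approx(sigma * np.sqrt(2), rel=0.05)

    def test_deterministic_given_seed(self, exp3, small_phantom):
        s1, sir1 = simulate_series(small_phantom, exp3, seed=9)
        s2, sir2 = simulate_series(small_phantom, exp3, seed=9)
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(sir1.data, sir2.data)

    def test_sir_contrast_ordering(self, small_phantom, small_subject):
        """SIR: WM bright, mixed intermediate, GM suppressed."""
        _, sir = small_subject
        wm = sir.data[small_phantom.wm_mask].mean()
        mixed = sir.data[small_phantom.class_mask(MIXED)].mean()
        gm = sir.data[small_phantom.gm_mask].mean()
        assert wm > mixed > gm
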