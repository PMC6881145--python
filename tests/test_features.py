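"""Feature extraction vs independent brute-force oracles and analytic
constructions."""

import numpy as np
import pytest

from conftest import make_step_sweep
from ieplast.features import (
    CellFeatures,
    ahp_feature,
    ap_threshold_feature,
    baseline,
    burst_index,
    detect_spikes,
    estimate_series_resistance,
    extract_features,
    first_spike_latency,
    input_resistance,
    qc_pass,
    sag_ratio,
    vm_variance,
)
from ieplast.sweep import Sweep


# ------------------------------------------------------------------ helpers

def random_hyper_sweep(rng: np.random.Generator, dt: float = 0.1) -> Sweep:
    """Random smooth hyperpolarizing sweep with RC-like course + noise."""
    amp = float(rng.choice([-300.0, -250.0, -200.0]))
    r_m = rng.uniform(30.0, 90.0) / 1000.0     # GOhm -> mV/pA
    tau = rng.uniform(10.0, 30.0)
    sag_frac = rng.uniform(0.0, 0.4)
    tau_sag = rng.uniform(40.0, 120.0)
    vb = rng.uniform(-70.0, -55.0)

    def course(t):
        charge = amp * r_m * (1 - np.exp(-t / tau))
        rebound = -sag_frac * amp * r_m * (1 - np.exp(-t / tau_sag))
        return vb + charge + rebound

    course.baseline = vb
    sw = make_step_sweep(course, dt=dt, amp=amp)
    sw.v = sw.v + rng.normal(0, 0.05, len(sw.v))
    return sw


def spike_train_sweep(spike_times_ms, dt=0.1, step_ms=300.0, vb=-60.0) -> Sweep:
    """Triangular spikes at given times (from onset) on a flat step."""
    n_pre = int(round(100.0 / dt))
    n_step = int(round(step_ms / dt))
    n_post = int(round(100.0 / dt))
    v = np.full(n_pre + n_step + n_post, vb)
    for t0 in spike_times_ms:
        k = n_pre + int(round(t0 / dt))
        up = np.linspace(vb, 30.0, int(1.0 / dt))        # 1-ms upstroke
        down = np.linspace(30.0, vb - 8.0, int(2.0 / dt))  # AHP dip
        rec = np.linspace(vb - 8.0, vb, int(20.0 / dt))
        wave = np.concatenate([up, down, rec])
        end = min(k + len(wave), len(v))
        v[k:end] = wave[: end - k]
    i = np.zeros_like(v)
    i[n_pre : n_pre + n_step] = 400.0
    return Sweep(dt=dt, v=v, i=i, step_onset=n_pre, step_offset=n_pre + n_step, step_amp=400.0)


# -------------------------------------------------------------- detect_spikes

class TestDetectSpikes:
    def test_constant_trace_gives_no_events(self):
        sw = Sweep(dt=0.1, v=np.full(5000, -60.0), i=np.zeros(5000), step_onset=0,
                   step_offset=5000, step_amp=0.0)
        assert detect_spikes(sw) == []

    def test_threshold_matches_bruteforce_dvdt_scan(self, rng):
        """Threshold sample equals the first rising-phase point where the
        central-difference dV/dt crosses 10 V/s (independent scan)."""
        for _ in range(25):
            t0 = float(rng.uniform(20.0, 250.0))
            sw = spike_train_sweep([t0], dt=0.1)
            events = detect_spikes(sw, peak_min_mV=-np.inf)
            assert len(events) == 1
            v = sw.v
            dvdt = np.empty(len(v))
            dvdt[1:-1] = (v[2:] - v[:-2]) / (2 * sw.dt)
            dvdt[0] = (v[1] - v[0]) / sw.dt
            dvdt[-1] = (v[-1] - v[-2]) / sw.dt
            # brute force: first index >= 10 V/s
            idx = next(k for k in range(len(v)) if dvdt[k] >= 10.0)
            assert events[0].t_threshold == pytest.approx(idx * sw.dt)

    def test_two_spikes_ordered(self):
        sw = spike_train_sweep([50.0, 55.0])
        events = detect_spikes(sw)
        assert len(events) == 2
        assert events[0].t_peak < events[1].t_threshold

    def test_peak_is_local_maximum(self):
        sw = spike_train_sweep([100.0])
        (e,) = detect_spikes(sw)
        assert e.v_peak == pytest.approx(30.0, abs=0.5)
        assert e.v_peak > e.v_threshold

    def test_coarse_dt_warns(self):
        sw = Sweep(dt=0.5, v=np.full(1000, -60.0), i=np.zeros(1000), step_onset=0,
                   step_offset=1000, step_amp=0.0)
        with pytest.warns(RuntimeWarning):
            detect_spikes(sw)


# ------------------------------------------------------------ input resistance

class TestInputResistance:
    def test_simple_arithmetic(self):
        """-300 pA with a -15 mV minimum deflection is 50 MOhm."""
        def course(t):
            return -60.0 - 15.0 * (1 - np.exp(-t / 5.0))
        course.baseline = -60.0
        sw = make_step_sweep(course, amp=-300.0)
        assert input_resistance([sw]) == pytest.approx(50.0, rel=0.01)

    def test_pure_rc_recovers_construction(self):
        """RC course (tau 20 ms, R 60 MOhm) on a 300-ms step."""
        for amp in (-300.0, -250.0, -200.0):
            def course(t, amp=amp):
                return -60.0 + amp * 0.060 * (1 - np.exp(-t / 20.0))
            course.baseline = -60.0
            sw = make_step_sweep(course, amp=amp)
            assert input_resistance([sw]) == pytest.approx(60.0, rel=0.01)

    def test_uses_minimum_not_steady_state(self):
        """With sag, the minimum within 150 ms (not the final value) sets Rin."""
        def course(t):
            # dips to -18 mV around 60 ms, relaxes to -12 mV
            return -60.0 - 18.0 * (1 - np.exp(-t / 15.0)) + 6.0 * (1 - np.exp(-t / 80.0))
        course.baseline = -60.0
        sw = make_step_sweep(course, amp=-300.0)
        # brute-force scan over the first 150 ms
        i1 = sw.step_onset + int(round(150.0 / sw.dt))
        vmin = sw.v[sw.step_onset : i1].min()
        expected = (vmin - (-60.0)) / -300.0 * 1000.0
        assert input_resistance([sw]) == pytest.approx(expected, rel=1e-9)

    def test_requires_hyperpolarizing_sweeps(self):
        def course(t):
            return -60.0 + 10.0 * (1 - np.exp(-t / 20.0))
        course.baseline = -60.0
        with pytest.raises(ValueError):
            input_resistance([make_step_sweep(course, amp=300.0)])

    def test_oracle_equivalence_randomized(self, rng):
        """Feature equals a brute-force reimplementation on >= 100 random
        synthetic sweeps (mean traces per amplitude, then median)."""
        for _ in range(20):
            sweeps = [random_hyper_sweep(rng) for _ in range(6)]
            got = input_resistance(sweeps)
            # brute force
            groups = {}
            for s in sweeps:
                groups.setdefault(s.step_amp, []).append(s)
            per_amp = []
            for amp, sws in groups.items():
                v = np.mean([s.v for s in sws], axis=0)
                ref = sws[0]
                nb = int(round(50.0 / ref.dt))
                base = v[ref.step_onset - nb : ref.step_onset].mean()
                i1 = ref.step_onset + int(round(150.0 / ref.dt))
                per_amp.append((v[ref.step_onset : i1].min() - base) / amp * 1000.0)
            assert got == pytest.approx(np.median(per_amp), rel=1e-12)


# ------------------------------------------------------------------ sag ratio

class TestSagRatio:
    def test_simple_arithmetic(self):
        """Steady -10 mV over minimum -15 mV is 2/3."""
        def course(t):
            # dip to -15 mV within 100 ms, then relax to a -10 mV plateau
            dip = -15.0 * (1 - np.exp(-t / 3.0))
            rebound = np.where(t >= 100.0, 5.0 * (1 - np.exp(-(t - 100.0) / 20.0)), 0.0)
            return -60.0 + dip + rebound
        course.baseline = -60.0
        sw = make_step_sweep(course, amp=-300.0)
        ratio = sag_ratio([sw])
        # brute force on the same samples
        nb = int(round(50.0 / sw.dt))
        base = sw.v[sw.step_onset - nb : sw.step_onset].mean()
        i1 = sw.step_onset + int(round(150.0 / sw.dt))
        vmin = sw.v[sw.step_onset : i1].min() - base
        n50 = int(round(50.0 / sw.dt))
        steady = np.median(sw.v[sw.step_offset - n50 : sw.step_offset]) - base
        assert ratio == pytest.approx(steady / vmin, rel=1e-12)
        assert ratio == pytest.approx(10.0 / 15.0, rel=0.02)

    def test_offset_invariance(self, rng):
        """Rin and sag are invariant to a constant voltage offset."""
        sweeps = [random_hyper_sweep(rng) for _ in range(6)]
        shifted = [
            Sweep(dt=s.dt, v=s.v + 17.0, i=s.i, step_onset=s.step_onset,
                  step_offset=s.step_offset, step_amp=s.step_amp)
            for s in sweeps
        ]
        assert sag_ratio(shifted) == pytest.approx(sag_ratio(sweeps), rel=1e-9)
        assert input_resistance(shifted) == pytest.approx(input_resistance(sweeps), rel=1e-9)

    def test_zero_deflection_raises(self):
        def course(t):
            return -60.0 + 0.0 * t
        course.baseline = -60.0
        with pytest.raises(ZeroDivisionError):
            sag_ratio([make_step_sweep(course, amp=-300.0)])


# ---------------------------------------------------------- series resistance

class TestSeriesResistance:
    @staticmethod
    def two_compartment_sweep(rs_mohm, rm_mohm=50.0, amp=-250.0, tau_pip=0.4, tau_m=20.0):
        """Analytic pipette + membrane charging trace."""
        def course(t):
            drop = amp * rs_mohm / 1000.0 * (1 - np.exp(-t / tau_pip))
            charge = amp * rm_mohm / 1000.0 * (1 - np.exp(-t / tau_m))
            return -60.0 + drop + charge
        course.baseline = -60.0
        return make_step_sweep(course, dt=0.05, amp=amp)

    @pytest.mark.parametrize("rs", [5.0, 20.0, 50.0])
    def test_recovers_construction_within_5_percent(self, rs):
        sweeps = [self.two_compartment_sweep(rs, amp=a) for a in (-300.0, -250.0, -200.0)]
        est = estimate_series_resistance(sweeps)
        assert est == pytest.approx(rs, rel=0.05)

    def test_zero_instantaneous_drop_gives_zero(self):
        sweeps = [self.two_compartment_sweep(0.0, amp=a) for a in (-300.0, -200.0)]
        assert estimate_series_resistance(sweeps) == pytest.approx(0.0, abs=0.5)

    def test_duplicate_sweeps_do_not_change_result(self):
        sweeps = [self.two_compartment_sweep(20.0, amp=a) for a in (-300.0, -200.0)]
        est1 = estimate_series_resistance(sweeps)
        est2 = estimate_series_resistance(sweeps + sweeps)
        assert est2 == pytest.approx(est1, rel=1e-6)

    def test_single_amplitude_rejected(self):
        sweeps = [self.two_compartment_sweep(20.0, amp=-250.0)] * 3
        with pytest.raises(ValueError):
            estimate_series_resistance(sweeps)


# ------------------------------------------------------- threshold / AHP / latency

class TestSpikeFeatures:
    def test_threshold_median_across_sweeps(self):
        """Median of per-sweep first-spike thresholds (brute-force oracle)."""
        sweeps = [spike_train_sweep([t]) for t in (40.0, 80.0, 120.0)]
        got = ap_threshold_feature(sweeps)
        firsts = []
        for s in sweeps:
            events = [e for e in detect_spikes(s)
                      if s.step_onset * s.dt <= e.t_threshold < s.step_offset * s.dt]
            firsts.append(events[0].v_threshold)
        assert got == pytest.approx(np.median(firsts))

    def test_ahp_eligibility_rules(self):
        """A spike followed within 50 ms by another is excluded; the last
        spike is judged against the step end."""
        sw = spike_train_sweep([100.0, 130.0], step_ms=300.0)
        got = ahp_feature([sw])
        # first spike excluded (next threshold 30 ms later); second eligible
        events = [e for e in detect_spikes(sw)
                  if sw.step_onset * sw.dt <= e.t_threshold < sw.step_offset * sw.dt]
        e = events[1]
        i0 = int(round(e.t_threshold / sw.dt)) + 1
        i1 = int(round((e.t_threshold + 50.0) / sw.dt)) + 1
        assert got == pytest.approx(sw.v[i0:i1].min(), rel=1e-12)

    def test_ahp_excluded_when_step_ends_inside_window(self):
        sw = spike_train_sweep([280.0], step_ms=300.0)  # window ends at 330 > 300
        assert ahp_feature([sw]) is None

    def test_latency_mean_over_repeats(self):
        sweeps = [spike_train_sweep([20.0]), spike_train_sweep([30.0])]
        got = first_spike_latency(sweeps)
        assert got == pytest.approx(25.0, abs=0.2)

    def test_latency_ignores_silent_sweeps(self):
        sweeps = [spike_train_sweep([23.4]), spike_train_sweep([])]
        assert first_spike_latency(sweeps) == pytest.approx(23.4, abs=0.2)
        assert first_spike_latency([spike_train_sweep([])]) is None


# ---------------------------------------------------------------- burst index

class TestBurstIndex:
    def make(self, trains):
        return [spike_train_sweep(t) for t in trains]

    def test_all_short_isis_give_one(self):
        sweeps = self.make([[50, 55, 60, 65, 70, 75]])
        assert burst_index(sweeps) == pytest.approx(1.0)

    def test_all_long_isis_give_zero(self):
        sweeps = self.make([[20, 70, 120, 170, 220, 270]])
        assert burst_index(sweeps) == pytest.approx(0.0)

    def test_mixed_train_matches_pairwise_oracle(self):
        """ISIs {5, 50, 8, 60} ms: spikes 1,2 and 3,4 are in bursts -> 4/5."""
        times = [50.0, 55.0, 105.0, 113.0, 173.0]
        sweeps = self.make([times])
        got = burst_index(sweeps)
        # exhaustive oracle over ISI pairs
        in_burst = [False] * len(times)
        for i in range(len(times) - 1):
            if times[i + 1] - times[i] < 10.0:
                in_burst[i] = in_burst[i + 1] = True
        assert got == pytest.approx(sum(in_burst) / len(times))
        assert got == pytest.approx(0.8)

    def test_requires_mean_count_of_five(self):
        sweeps = self.make([[50, 55], [60, 66]])  # mean 2 spikes < 5
        assert burst_index(sweeps) is None

    def test_takes_highest_qualifying_amplitude(self):
        bursty = [spike_train_sweep([50, 55, 60, 65, 70], vb=-60.0)]
        for s in bursty:
            s.step_amp = 500.0
            s.i[s.step_onset:s.step_offset] = 500.0
        regular = self.make([[30, 80, 130, 180, 230]])
        assert burst_index(bursty + regular) == pytest.approx(1.0)


# ---------------------------------------------------------------- Vm variance

class TestVmVariance:
    def test_constant_trace_gives_zero(self):
        v = np.full(60000, -60.0)
        assert vm_variance(v, dt_ms=1.0, segment_s=5.0) == 0.0

    def test_white_noise_recovers_variance(self, rng):
        v = -60.0 + rng.normal(0, 0.5, 50000)
        got = vm_variance(v, dt_ms=1.0, segment_s=5.0, blank_spikes=False)
        assert got == pytest.approx(0.25, rel=0.1)

    def test_median_across_segments(self):
        """Segments with variances ~{0.1, 0.2, 0.9} yield the middle one."""
        rng = np.random.Generator(np.random.Philox(7))
        segs = [rng.normal(0, np.sqrt(s), 5000) for s in (0.1, 0.2, 0.9)]
        v = -60.0 + np.concatenate(segs)
        got = vm_variance(v, dt_ms=1.0, segment_s=5.0, blank_spikes=False)
        expected = np.median([np.var(s) for s in segs])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            vm_variance(np.zeros(100), dt_ms=1.0, segment_s=5.0)


# -------------------------------------------------------------------- QC

class TestQC:
    def make_feats(self, vm, rs, amp):
        return CellFeatures(vm_rest=vm, rs=rs, spike_amplitude=amp)

    @pytest.mark.parametrize(
        "vm,rs,amp,ok,bad",
        [
            (-62.0, 50.0, 55.0, True, []),
            (-50.0, 50.0, 55.0, False, ["vm_rest"]),
            (-62.0, 120.0, 55.0, False, ["rs"]),
            (-62.0, 50.0, 30.0, False, ["spike_amplitude"]),
            (-55.0, 100.0, 40.0, False, ["vm_rest", "rs", "spike_amplitude"]),
        ],
    )
    def test_criteria_and_boundaries(self, vm, rs, amp, ok, bad):
        passed, reasons = qc_pass(self.make_feats(vm, rs, amp))
        assert passed is ok
        assert reasons == bad


# --------------------------------------------------------------- composition

class TestExtractFeatures:
    def test_passive_cell_features(self, rng):
        """A passive construction yields the built-in Rin and no spike
        features."""
        sweeps = []
        for amp in (-300.0, -250.0, -200.0):
            def course(t, amp=amp):
                return -60.0 + amp * 0.050 * (1 - np.exp(-t / 15.0))
            course.baseline = -60.0
            sweeps.append(make_step_sweep(course, amp=amp))
        feats = extract_features(sweeps)
        assert feats.rin == pytest.approx(50.0, rel=0.01)
        assert feats.burst_index is None
        assert feats.ap_threshold is None
        assert "no_depolarizing_sweeps" in feats.flags

    def test_extraction_is_pure(self, rng):
        sweeps = [random_hyper_sweep(rng) for _ in range(4)] + [
            spike_train_sweep([40.0, 90.0, 140.0, 190.0, 240.0])
        ]
        f1 = extract_features(sweeps)
        f2 = extract_features(sweeps)
        assert f1 == f2
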