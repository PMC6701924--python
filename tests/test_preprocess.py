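import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smfretkin import preprocess as pp
from smfretkin import synthetic_data as sd
from smfretkin.trace_io import IntensityTrace


def flat_trace(n=100, donor=0.0, acceptor=0.0, noise=0.0, seed=0, record_id="r"):
    rng = np.random.default_rng(seed)
    dt = 2.67
    time = np.empty(2 * n)
    time[0::2] = np.arange(n) * dt
    time[1::2] = np.arange(n) * dt + dt / 2
    exc = np.array(["donor", "acceptor"] * n, dtype=object)
    d = np.full(2 * n, donor) + (rng.normal(0, noise, 2 * n) if noise else 0.0)
    a = np.full(2 * n, acceptor) + (rng.normal(0, noise, 2 * n) if noise else 0.0)
    return IntensityTrace(
        record_id=record_id, frame_index=np.arange(2 * n), time_s=time,
        excitation=exc, I_donor_em=d, I_acceptor_em=a, frame_interval=dt,
    )


class TestComputeEfret:
    @pytest.mark.parametrize(
        "ia,idn,expected", [(60, 40, 0.6), (0, 100, 0.0), (50, 50, 0.5)]
    )
    def test_values(self, ia, idn, expected):
        assert pp.compute_efret(ia, idn) == pytest.approx(expected)

    def test_zero_total_undefined(self):
        assert np.isnan(pp.compute_efret(0.0, 0.0))

    @given(
        ia=st.floats(-100, 100, allow_nan=False),
        idn=st.floats(-100, 100, allow_nan=False),
        c=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, ia, idn, c):
        e1 = pp.compute_efret(ia, idn)
        e2 = pp.compute_efret(c * ia, c * idn)
        if np.isfinite(e1) and np.isfinite(e2):
            assert e2 == pytest.approx(e1, rel=1e-9, abs=1e-9)


class TestDetectPresence:
    def test_noiseless_step_single_interval(self):
        tr = flat_trace(n=120)
        dmask = tr.donor_mask
        # spot on donor channel frames 30..79 (50 frames)
        idx = np.nonzero(dmask)[0][30:80]
        tr.I_donor_em[idx] += 100.0
        pres = pp.detect_presence_intervals(tr, threshold_sd=4, min_dwell_frames=3)
        assert len(pres.donor) == 1
        a, b = pres.donor[0]
        assert a == pytest.approx(30 * 2.67)
        assert b == pytest.approx(80 * 2.67)
        assert pres.acceptor == []

    def test_pure_noise_no_intervals(self):
        # oracle: P(single-frame z > 5) ~ 2.9e-7; runs of 3 essentially never
        hits = 0
        for seed in range(1000):
            tr = flat_trace(n=200, noise=5.0, seed=seed)
            pres = pp.detect_presence_intervals(tr, threshold_sd=5, min_dwell_frames=3)
            hits += bool(pres.donor or pres.acceptor)
        assert hits <= 10  # zero intervals in >= 99% of traces

    def test_constant_trace_no_intervals(self):
        tr = flat_trace(n=50, donor=7.0)
        pres = pp.detect_presence_intervals(tr)
        assert pres.donor == [] and pres.acceptor == []

    def test_arrival_recovery_at_snr10(self):
        cfg = sd.SimulationConfig(
            scheme=sd.wt_like_scheme(),
            emission=sd.EmissionConfig(
                efret_levels=np.array([0.03, 0.61, 0.03]),
                total_intensity=100.0, noise_sd=10.0,
                donor_bleach_rate=1 / 900.0, acceptor_bleach_rate=1 / 900.0,
            ),
            n_records=100, rng_seed=21,
        )
        ts, truth = sd.simulate_dataset(cfg)
        ok = total = 0
        for tr, rec in zip(ts, truth.records):
            pres = pp.detect_presence_intervals(tr, threshold_sd=4, min_dwell_frames=3)
            if len(pres.acceptor) != 1:
                continue
            total += 1
            ok += abs(pres.acceptor[0][0] - rec.acceptor_arrival) <= 2 * 2.67
        assert total >= 80
        assert ok / total >= 0.95


class TestSubtractBaseline:
    def _with_spot(self, baseline, drift_end=0.0, n=200):
        tr = flat_trace(n=n, donor=baseline, acceptor=baseline)
        drift = np.linspace(0, drift_end, 2 * n)
        tr.I_donor_em = tr.I_donor_em + drift
        tr.I_acceptor_em = tr.I_acceptor_em + drift
        dmask = tr.donor_mask
        idx = np.nonzero(dmask)[0][50:120]
        tr.I_donor_em[idx] += 100.0
        pres = pp.PresenceIntervals(
            donor=[(50 * 2.67, 120 * 2.67)], acceptor=[]
        )
        return tr, pres, idx

    def test_constant_baseline_removed(self):
        tr, pres, idx = self._with_spot(baseline=50.0)
        out = pp.subtract_baseline(tr, pres, smooth_window_frames=15)
        np.testing.assert_allclose(out.I_donor_em[idx], 100.0, atol=1e-9)
        base_idx = np.setdiff1d(np.nonzero(tr.donor_mask)[0], idx)
        np.testing.assert_allclose(out.I_donor_em[base_idx], 0.0, atol=1e-9)

    def test_linear_drift_removed(self):
        tr, pres, idx = self._with_spot(baseline=0.0, drift_end=20.0)
        out = pp.subtract_baseline(tr, pres, smooth_window_frames=15)
        base_idx = np.setdiff1d(np.nonzero(tr.donor_mask)[0], idx)
        assert np.abs(out.I_donor_em[base_idx].mean()) < 1.0

    def test_spotless_trace_zeroed(self):
        tr = flat_trace(n=100, donor=13.0, acceptor=4.0)
        pres = pp.PresenceIntervals(donor=[], acceptor=[])
        out = pp.subtract_baseline(tr, pres)
        np.testing.assert_allclose(out.I_donor_em, 0.0, atol=1e-9)
        np.testing.assert_allclose(out.I_acceptor_em, 0.0, atol=1e-9)

    def test_no_baseline_frames_errors(self):
        tr = flat_trace(n=20)
        pres = pp.PresenceIntervals(donor=[(0.0, 1e6)], acceptor=[])
        with pytest.raises(ValueError, match="baseline"):
            pp.subtract_baseline(tr, pres)


class TestSelection:
    def test_two_donor_arrivals_excluded(self):
        tr = flat_trace(n=50, record_id="r0")
        pres = {
            "r0": pp.PresenceIntervals(
                donor=[(0.0, 20.0), (40.0, 60.0)], acceptor=[(0.0, 60.0)]
            )
        }
        from smfretkin.trace_io import TraceSet

        recs, report = pp.select_two_hexamer_records(TraceSet(traces=[tr]), pres)
        assert recs == []
        assert "donor count != 1" in report["reason"].iloc[0]

    def test_later_arrival_is_t0(self):
        tr = flat_trace(n=100, donor=50.0, acceptor=30.0, record_id="r0")
        pres = {
            "r0": pp.PresenceIntervals(
                donor=[(30.0, 250.0)], acceptor=[(75.0, 250.0)]
            )
        }
        from smfretkin.trace_io import TraceSet

        recs, _ = pp.select_two_hexamer_records(TraceSet(traces=[tr]), pres)
        assert len(recs) == 1
        # first donor-excitation frame at or after 75 s
        assert recs[0].t0 == pytest.approx(np.ceil(75.0 / 2.67) * 2.67, abs=2.67)
        assert recs[0].t0 >= 75.0 - 1e-9

    def test_simulated_cohort_selection_recovery(self):
        cfg = sd.SimulationConfig(
            scheme=sd.wt_like_scheme(),
            emission=sd.EmissionConfig(
                efret_levels=np.array([0.03, 0.61, 0.03]),
                total_intensity=200.0, noise_sd=10.0,
                donor_bleach_rate=1 / 900.0, acceptor_bleach_rate=1 / 900.0,
            ),
            n_records=200, rng_seed=31,
        )
        ts, truth = sd.simulate_dataset(cfg)
        records, excl, _ = pp.preprocess_traceset(ts)
        # ground-truth qualifying records: both complexes coexist >= 4 frames
        qualify = {
            r.record_id
            for r in truth.records
            if r.t_end - r.t0 >= 4 * 2.67
        }
        got = {r.record_id for r in records}
        assert len(got & qualify) / len(qualify) >= 0.95


class TestOutlierPolicy:
    def _rec(self, efret, record_id="r"):
        return pp.EfretRecord(
            record_id=record_id, t0=0.0, efret=np.asarray(efret, dtype=float),
            frame_interval=2.67,
        )

    def test_drop_when_over_limit(self):
        vals = np.full(50, 0.5)
        vals[:11] = 0.95
        kept, report = pp.apply_outlier_policy([self._rec(vals)])
        assert kept == []
        assert report["dropped"].iloc[0]

    def test_keep_at_limit(self):
        vals = np.full(50, 0.5)
        vals[:10] = 0.95
        kept, _ = pp.apply_outlier_policy([self._rec(vals)])
        assert len(kept) == 1
        assert kept[0].n_outliers == 10

    def test_boundary_masking(self):
        kept, _ = pp.apply_outlier_policy([self._rec([0.9, 0.5, -0.3, 0.85, -0.25])])
        mask = kept[0].outlier_mask
        assert list(mask) == [True, False, True, False, False]

    def test_injected_outlier_fraction_recovered(self):
        rng = np.random.default_rng(8)
        recs = []
        total = n_out = 0
        for i in range(100):
            vals = rng.normal(0.5, 0.05, 200)
            inject = rng.random(200) < 0.035
            vals[inject] = 1.5
            total += 200
            n_out += inject.sum()
            recs.append(self._rec(vals, record_id=f"r{i}"))
        kept, report = pp.apply_outlier_policy(recs, max_outliers=10_000)
        observed = report["n_outliers"].sum() / report["n_frames"].sum()
        se = np.sqrt(0.035 * 0.965 / total)
        assert abs(observed - 0.035) < 4 * se

    def test_policy_idempotent(self):
        vals = np.linspace(-0.5, 1.0, 40)
        kept1, _ = pp.apply_outlier_policy([self._rec(vals)], max_outliers=100)
        kept2, _ = pp.apply_outlier_policy(kept1, max_outliers=100)
        np.testing.assert_array_equal(kept1[0].outlier_mask, kept2[0].outlier_mask)
        np.testing.assert_array_equal(kept1[0].efret, kept2[0].efret)


class TestPipeline:
    def test_noiseless_pipeline_recovers_levels(self):
        levels = np.array([0.03, 0.61, 0.03])
        cfg = sd.SimulationConfig(
            scheme=sd.wt_like_scheme(refractory_fraction=0.0),
            emission=sd.EmissionConfig(
                efret_levels=levels, total_intensity=200.0, noise_sd=0.0,
                donor_bleach_rate=1 / 900.0, acceptor_bleach_rate=1 / 900.0,
            ),
            n_records=20, rng_seed=13,
        )
        ts, truth = sd.simulate_dataset(cfg)
        records, _, _ = pp.preprocess_traceset(ts)
        truth_by_id = {r.record_id: r for r in truth.records}
        assert len(records) >= 10
        checked = 0
        for rec in records:
            tp = truth_by_id[rec.record_id]
            if abs(rec.t0 - tp.t0) > 1e-6:
                continue
            n = min(len(rec), len(tp.path))
            np.testing.assert_allclose(
                rec.efret[:n], levels[tp.path.states[:n]], atol=1e-9
            )
            checked += 1
        assert checked >= 5
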