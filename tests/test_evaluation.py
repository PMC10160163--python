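"""Velocity-field comparison metrics."""

import numpy as np
import pytest

from cineflow.evaluation import (
    angle_error,
    cohort_metrics,
    relative_error,
    threshold_accuracy,
    threshold_sweep,
    velocity_epe,
    velocity_histogram,
    velocity_pcc,
)
from cineflow.losses import epe_loss
from cineflow.preprocess import displacement_to_velocity, velocity_to_displacement
from cineflow.types import AcquisitionMeta, BloodPoolMask, DegenerateInputError, FlowField


def _field(vx, vy):
    return FlowField(vx=np.asarray(vx, float), vy=np.asarray(vy, float))


def _uniform(T, H, W, vx, vy):
    return _field(np.full((T, H, W), vx), np.full((T, H, W), vy))


def _full_mask(T, H, W, label=1):
    return BloodPoolMask(labels=np.full((T, H, W), label, dtype=int))


def brute_force_velocity_metrics(pred, ref, mask, vmin):
    """Scalar double-loop oracle for EPE and angle error."""
    epe_sum = ang_sum = 0.0
    n = 0
    T, H, W = ref.shape
    for t in range(T):
        for r in range(H):
            for c in range(W):
                if not mask.labels[t, r, c]:
                    continue
                gx, gy = ref.vx[t, r, c], ref.vy[t, r, c]
                if (gx * gx + gy * gy) ** 0.5 <= vmin:
                    continue
                px, py = pred.vx[t, r, c], pred.vy[t, r, c]
                epe_sum += ((px - gx) ** 2 + (py - gy) ** 2) ** 0.5
                dot = px * gx + py * gy
                norms = ((px**2 + py**2) ** 0.5) * ((gx**2 + gy**2) ** 0.5)
                ang_sum += np.degrees(np.arccos(max(-1.0, min(1.0, dot / norms))))
                n += 1
    return epe_sum / n, ang_sum / n


class TestVelocityEpe:
    def test_identical_fields_zero(self, rng):
        f = _field(rng.random((2, 4, 4)) * 20, rng.random((2, 4, 4)) * 20)
        assert velocity_epe(f, f, _full_mask(2, 4, 4)) == 0.0

    def test_single_pixel_hand_example(self):
        # pred (10,0), ref (6,8): sqrt(16+64) = sqrt(80)
        pred = _uniform(1, 1, 1, 10.0, 0.0)
        ref = _uniform(1, 1, 1, 6.0, 8.0)
        assert velocity_epe(pred, ref, _full_mask(1, 1, 1)) == pytest.approx(
            np.sqrt(80), abs=1e-12
        )

    def test_infinite_threshold_is_degenerate(self):
        f = _uniform(1, 2, 2, 10.0, 0.0)
        with pytest.raises(DegenerateInputError):
            velocity_epe(f, f, _full_mask(1, 2, 2), vmin=np.inf)

    def test_matches_brute_force_oracle(self, rng):
        pred = _field(rng.standard_normal((2, 6, 6)) * 10, rng.standard_normal((2, 6, 6)) * 10)
        ref = _field(rng.standard_normal((2, 6, 6)) * 10, rng.standard_normal((2, 6, 6)) * 10)
        mask = BloodPoolMask(labels=(rng.random((2, 6, 6)) > 0.3).astype(int))
        e, a = brute_force_velocity_metrics(pred, ref, mask, 5.0)
        assert velocity_epe(pred, ref, mask) == pytest.approx(e, abs=1e-9)
        assert angle_error(pred, ref, mask)[0] == pytest.approx(a, abs=1e-9)

    def test_consistent_with_displacement_epe_under_unit_conversion(self, rng):
        """Velocity EPE equals displacement EPE converted through dt/ps when
        pixel spacing is isotropic."""
        meta = AcquisitionMeta((1.5, 1.5), 0.04, 60.0, 3)
        pred = _field(rng.standard_normal((3, 4, 4)) * 10, rng.standard_normal((3, 4, 4)) * 10)
        ref = _field(rng.standard_normal((3, 4, 4)) * 10, rng.standard_normal((3, 4, 4)) * 10)
        mask = _full_mask(3, 4, 4)
        dp = velocity_to_displacement(pred, meta)
        dg = velocity_to_displacement(ref, meta)
        disp_epe = np.mean(
            [
                epe_loss(
                    np.stack([dp.dx[t], dp.dy[t]]),
                    np.stack([dg.dx[t], dg.dy[t]]),
                    mask.binary()[t],
                )
                for t in range(3)
            ]
        )
        vel_epe = velocity_epe(pred, ref, mask, vmin=-1.0)
        factor = 1.5 / 0.04 / 10.0  # ps / dt, mm/s -> cm/s
        assert vel_epe == pytest.approx(disp_epe * factor, rel=1e-9)


class TestAngleError:
    def test_parallel_zero_opposite_180_orthogonal_90(self):
        ref = _uniform(1, 2, 2, 0.0, 6.0)
        assert angle_error(ref, ref, _full_mask(1, 2, 2))[0] == pytest.approx(0.0)
        opp = _uniform(1, 2, 2, 0.0, -6.0)
        assert angle_error(opp, ref, _full_mask(1, 2, 2))[0] == pytest.approx(180.0)
        orth = _uniform(1, 2, 2, 6.0, 0.0)
        assert angle_error(orth, ref, _full_mask(1, 2, 2))[0] == pytest.approx(90.0)

    def test_range_and_scale_invariance(self, rng):
        pred = _field(rng.standard_normal((2, 5, 5)) * 8, rng.standard_normal((2, 5, 5)) * 8)
        ref = _field(rng.standard_normal((2, 5, 5)) * 8 + 6, rng.standard_normal((2, 5, 5)) * 8)
        mask = _full_mask(2, 5, 5)
        a1, _ = angle_error(pred, ref, mask)
        assert 0.0 <= a1 <= 180.0
        scaled = _field(3.7 * pred.vx, 3.7 * pred.vy)
        a2, _ = angle_error(scaled, ref, mask)
        assert a1 == pytest.approx(a2, abs=1e-9)

    def test_zero_magnitude_prediction_excluded_with_count(self):
        ref = _uniform(1, 2, 1, 0.0, 10.0)
        pred = _field([[[0.0], [3.0]]], [[[0.0], [4.0]]])  # one zero, one nonzero
        ang, excluded = angle_error(pred, ref, _full_mask(1, 2, 1))
        assert excluded == 1
        assert ang == pytest.approx(np.degrees(np.arccos(4 / 5)))


class TestRelativeError:
    def test_identical_zero_and_half_scale(self, rng):
        ref = _field(rng.random((2, 4, 4)) * 10 + 1, rng.random((2, 4, 4)) * 10)
        assert relative_error(ref, ref, _full_mask(2, 4, 4)) == pytest.approx(0.0)
        half = _field(0.5 * ref.vx, 0.5 * ref.vy)
        assert relative_error(half, ref, _full_mask(2, 4, 4)) == pytest.approx(-50.0)

    def test_means_ratio_definition(self):
        # pred speeds {1, 3}, ref speeds {2, 2}: means equal -> 0 %
        pred = _field([[[1.0], [3.0]]], [[[0.0], [0.0]]])
        ref = _uniform(1, 2, 1, 2.0, 0.0)
        assert relative_error(pred, ref, _full_mask(1, 2, 1)) == pytest.approx(0.0)


class TestPcc:
    def _mask(self, T):
        return _full_mask(T, 2, 2)

    def test_identical_series_one(self):
        vx = np.arange(1.0, 6.0)[:, None, None] * np.ones((5, 2, 2))
        f = _field(vx, np.zeros_like(vx))
        assert velocity_pcc(f, f, self._mask(5)) == pytest.approx(1.0)

    def test_proportional_series_one_and_linear_hand_case(self):
        vx = np.array([1.0, 2.0, 3.0])[:, None, None] * np.ones((3, 2, 2))
        f1 = _field(vx, np.zeros_like(vx))
        f2 = _field(2 * vx, np.zeros_like(vx))
        assert velocity_pcc(f2, f1, self._mask(3)) == pytest.approx(1.0)

    def test_anticorrelated_series_minus_one(self):
        vx = np.array([1.0, 2.0, 3.0])[:, None, None] * np.ones((3, 2, 2))
        f1 = _field(vx, np.zeros_like(vx))
        f2 = _field(vx[::-1].copy(), np.zeros_like(vx))
        assert velocity_pcc(f2, f1, self._mask(3)) == pytest.approx(-1.0)

    def test_zero_variance_reported_absent(self):
        f = _uniform(3, 2, 2, 5.0, 0.0)
        assert velocity_pcc(f, f, self._mask(3)) is None


class TestHistogram:
    def test_single_bin_all_mass(self):
        f = _uniform(2, 3, 3, 10.0, 0.0)
        h = velocity_histogram(f, _full_mask(2, 3, 3), [0.0, 20.0])
        assert h.probability.tolist() == [1.0]

    def test_two_equal_groups_split_half_half(self):
        pred = _field([[[1.0], [11.0]]], [[[0.0], [0.0]]])
        h = velocity_histogram(pred, _full_mask(1, 2, 1), [0.0, 10.0, 20.0])
        assert h.probability.tolist() == [0.5, 0.5]

    def test_random_field_mass_sums_to_one_with_out_of_range_folding(self, rng):
        f = _field(rng.standard_normal((2, 8, 8)) * 30, rng.standard_normal((2, 8, 8)) * 30)
        h = velocity_histogram(f, _full_mask(2, 8, 8), np.linspace(0, 10, 6))
        assert h.probability.sum() == pytest.approx(1.0)


class TestThresholdSweep:
    def test_single_threshold_matches_direct_metrics(self, rng):
        pred = _field(rng.standard_normal((2, 6, 6)) * 10, rng.standard_normal((2, 6, 6)) * 10)
        ref = _field(rng.standard_normal((2, 6, 6)) * 10, rng.standard_normal((2, 6, 6)) * 10)
        mask = _full_mask(2, 6, 6)
        rows = threshold_sweep(pred, ref, mask, [5.0])
        assert rows[0]["epe"] == pytest.approx(velocity_epe(pred, ref, mask))
        assert rows[0]["angle_error"] == pytest.approx(angle_error(pred, ref, mask)[0])

    def test_perfect_prediction_zero_epe_and_monotone_counts(self, rng):
        ref = _field(rng.random((2, 6, 6)) * 30, rng.random((2, 6, 6)) * 30)
        mask = _full_mask(2, 6, 6)
        rows = threshold_sweep(ref, ref, mask, [0.0, 5.0, 10.0, 20.0, 100.0])
        counts = [r["n_pixels"] for r in rows]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        for r in rows:
            assert r["epe"] in (None, pytest.approx(0.0))
        assert rows[-1]["epe"] is None  # nothing exceeds 100 cm/s


class TestThresholdAccuracy:
    def test_perfect_prediction_is_fully_accurate(self, rng):
        ref = _field(rng.random((2, 6, 6)) * 20 + 1, rng.random((2, 6, 6)) * 20)
        assert threshold_accuracy(ref, ref, _full_mask(2, 6, 6)) == 1.0

    def test_large_errors_score_zero(self, rng):
        ref = _field(rng.random((2, 6, 6)) * 20 + 1, rng.random((2, 6, 6)) * 20)
        far = _field(ref.vx + 1000.0, ref.vy)
        assert threshold_accuracy(far, ref, _full_mask(2, 6, 6)) == 0.0


class TestCohortAggregation:
    def test_chamber_pixel_counts_sum_to_aggregate(self, tiny_phantom):
        mask = tiny_phantom.mask
        total = mask.binary().sum()
        per_chamber = sum(mask.chamber(label).sum() for label in (1, 2, 3, 4))
        assert per_chamber == total

    def test_cohort_report_structure(self, tiny_phantom, rng):
        truth = tiny_phantom.truth
        noisy = _field(truth.vx + 0.5, truth.vy - 0.5)
        report = cohort_metrics(
            {"a": noisy, "b": truth}, {"a": truth, "b": truth}, {"a": tiny_phantom.mask, "b": tiny_phantom.mask},
            vmin=1.0,
        )
        assert set(report.rows) == {"4CH", "LV", "LA", "RV", "RA"}
        assert report.rows["RV"]["n_cases"] == 0  # two-chamber phantom
        assert report.rows["4CH"]["epe_mean"] is not None
        df = report.to_frame()
        assert "epe_mean" in df.columns
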