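"""Intensity normalization, unit conversions, heart-rate screen, projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cineflow.preprocess import (
    PlaneGeometry,
    check_heart_rate,
    displacement_to_velocity,
    normalize_intensities,
    project_volume_velocity,
    velocity_to_displacement,
)
from cineflow.types import (
    AcquisitionMeta,
    BloodPoolMask,
    CineSequence,
    DegenerateInputError,
    DisplacementField,
    FlowField,
)


class TestNormalization:
    def test_uniform_0_to_100_maps_midpoint_to_half(self, meta):
        # sorted-percentile oracle: p5 = 5, p95 = 95 for {0..100}
        values = np.arange(101.0)[None, :]
        meta3 = AcquisitionMeta((1.0, 1.0), 0.04, 60.0, 3)
        seq = CineSequence(frames=np.tile(values, (3, 1, 1)), meta=meta3)
        mask = BloodPoolMask(labels=np.ones((3, 1, 101), dtype=int))
        normed, stats = normalize_intensities(seq, mask)
        assert stats.p5 == pytest.approx(5.0) and stats.p95 == pytest.approx(95.0)
        assert normed.frames[0, 0, 50] == pytest.approx((50 - 5) / 90)

    def test_percentile_endpoints_map_to_zero_and_one(self, rng):
        meta3 = AcquisitionMeta((1.0, 1.0), 0.04, 60.0, 3)
        seq = CineSequence(frames=rng.random((3, 8, 8)) * 40 + 5, meta=meta3)
        mask = BloodPoolMask(labels=np.ones((3, 8, 8), dtype=int))
        normed, stats = normalize_intensities(seq, mask)
        back = normed.frames * (stats.p95 - stats.p5) + stats.p5
        assert np.allclose(back, seq.frames)
        # applying the formula at the percentile values themselves
        assert (stats.p5 - stats.p5) / (stats.p95 - stats.p5) == 0.0
        # tails are preserved, not clipped
        assert normed.frames.min() < 0.0 and normed.frames.max() > 1.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0), st.integers(0, 10_000))
    def test_invariant_under_positive_affine_rescale(self, a, b, seed):
        rng = np.random.default_rng(seed)
        meta3 = AcquisitionMeta((1.0, 1.0), 0.04, 60.0, 3)
        frames = rng.random((3, 6, 6)) * 100
        mask = BloodPoolMask(labels=(rng.random((3, 6, 6)) > 0.4).astype(int))
        if not mask.binary().any():
            return
        n1, _ = normalize_intensities(CineSequence(frames=frames, meta=meta3), mask)
        n2, _ = normalize_intensities(CineSequence(frames=a * frames + b, meta=meta3), mask)
        assert np.allclose(n1.frames, n2.frames, atol=1e-9)

    def test_constant_masked_intensity_is_degenerate(self, meta):
        meta3 = AcquisitionMeta((1.0, 1.0), 0.04, 60.0, 3)
        seq = CineSequence(frames=np.full((3, 4, 4), 7.0), meta=meta3)
        mask = BloodPoolMask(labels=np.ones((3, 4, 4), dtype=int))
        with pytest.raises(DegenerateInputError):
            normalize_intensities(seq, mask)


class TestUnitConversion:
    def test_hand_evaluated_example(self):
        # 2.5 cm/s = 25 mm/s; 25 * 0.04 / 1.25 = 0.8 px
        meta = AcquisitionMeta((1.25, 1.25), 0.04, 60.0, 3)
        v = FlowField(vx=np.full((3, 2, 2), 2.5), vy=np.zeros((3, 2, 2)))
        d = velocity_to_displacement(v, meta)
        assert np.allclose(d.dx, 0.8) and np.allclose(d.dy, 0.0)

    def test_inverse_hand_example(self):
        meta = AcquisitionMeta((1.0, 1.0), 0.05, 60.0, 3)
        d = DisplacementField(dx=np.ones((3, 2, 2)), dy=np.zeros((3, 2, 2)))
        v = displacement_to_velocity(d, meta)
        assert np.allclose(v.vx, 2.0)  # 1 px * 1 mm / 0.05 s = 20 mm/s = 2 cm/s

    def test_zero_and_linearity(self, meta):
        z = FlowField(vx=np.zeros((3, 2, 2)), vy=np.zeros((3, 2, 2)))
        meta3 = AcquisitionMeta((1.25, 1.25), 0.04, 60.0, 3)
        d = velocity_to_displacement(z, meta3)
        assert not d.dx.any() and not d.dy.any()
        v = FlowField(vx=np.full((3, 2, 2), 3.0), vy=np.full((3, 2, 2), -1.0))
        d1 = velocity_to_displacement(v, meta3)
        neg = FlowField(vx=-v.vx, vy=-v.vy)
        d2 = velocity_to_displacement(neg, meta3)
        assert np.allclose(d1.dx, -d2.dx) and np.allclose(d1.dy, -d2.dy)

    def test_roundtrip_to_1e10_relative(self, rng):
        meta3 = AcquisitionMeta((0.95, 1.25), 0.0347, 72.0, 3)
        v = FlowField(vx=rng.standard_normal((3, 5, 5)) * 30, vy=rng.standard_normal((3, 5, 5)) * 30)
        back = displacement_to_velocity(velocity_to_displacement(v, meta3), meta3)
        assert np.allclose(back.vx, v.vx, rtol=1e-10, atol=1e-12)
        assert np.allclose(back.vy, v.vy, rtol=1e-10, atol=1e-12)


class TestHeartRateScreen:
    @pytest.mark.parametrize(
        "hr_cine,hr_flow,expected",
        [(70, 77, "exclude"), (70, 76, "keep"), (70, 70, "keep"), (76, 70, "keep"), (60, 80, "exclude")],
    )
    def test_six_bpm_rule_is_strict(self, hr_cine, hr_flow, expected):
        assert check_heart_rate(hr_cine, hr_flow) == expected


class TestVolumeProjection:
    def _volume(self, nx=5, ny=5, nz=5):
        vol = np.zeros((nx, ny, nz, 3))
        return vol

    def test_plane_on_grid_slice_reproduces_slice(self):
        rng = np.random.default_rng(0)
        vol = rng.standard_normal((5, 6, 4, 3))
        plane = PlaneGeometry(
            origin=(0.0, 0.0, 2.0),
            e_x=(1.0, 0.0, 0.0),
            e_y=(0.0, 1.0, 0.0),
            pixel_spacing=(1.0, 1.0),
            extent=(6, 5),
        )
        vx, vy, oob = project_volume_velocity(vol, (1.0, 1.0, 1.0), plane)
        assert oob == 0
        # pixel (r, c) sits at world (c, r, 2) -> volume node [c, r, 2]
        expected = vol[:, :, 2, :]
        assert np.allclose(vx, expected[..., 0].T)
        assert np.allclose(vy, expected[..., 1].T)

    def test_midpoint_of_two_nodes_is_arithmetic_mean(self):
        vol = np.zeros((2, 1, 1, 3))
        vol[0, 0, 0] = [1.0, 2.0, 3.0]
        vol[1, 0, 0] = [3.0, 6.0, 9.0]
        plane = PlaneGeometry(
            origin=(0.5, 0.0, 0.0),
            e_x=(1.0, 0.0, 0.0),
            e_y=(0.0, 1.0, 0.0),
            pixel_spacing=(1.0, 1.0),
            extent=(1, 1),
        )
        vx, vy, oob = project_volume_velocity(vol, (1.0, 1.0, 1.0), plane)
        assert vx[0, 0] == pytest.approx(2.0) and vy[0, 0] == pytest.approx(4.0)

    def test_out_of_plane_velocity_projects_to_zero(self):
        vol = np.zeros((4, 4, 4, 3))
        vol[..., 2] = 5.0  # purely along z
        plane = PlaneGeometry(
            origin=(0.0, 0.0, 1.0),
            e_x=(1.0, 0.0, 0.0),
            e_y=(0.0, 1.0, 0.0),
            pixel_spacing=(1.0, 1.0),
            extent=(3, 3),
        )
        vx, vy, _ = project_volume_velocity(vol, (1.0, 1.0, 1.0), plane)
        assert not vx.any() and not vy.any()

    def test_exact_on_trilinear_fields_and_oob_count(self):
        # trilinear interpolation reproduces any trilinear function exactly
        n = 4
        xs, ys, zs = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
        f = 2.0 + 0.5 * xs - 1.5 * ys + 0.25 * zs + 0.1 * xs * ys - 0.2 * ys * zs
        vol = np.stack([f, 2 * f, np.zeros_like(f)], axis=-1).astype(float)
        plane = PlaneGeometry(
            origin=(0.3, 0.2, 1.1),
            e_x=(1.0, 0.0, 0.0),
            e_y=(0.0, 1.0, 0.0),
            pixel_spacing=(0.7, 0.6),
            extent=(4, 8),
        )
        vx, vy, oob = project_volume_velocity(vol, (1.0, 1.0, 1.0), plane)
        coords = plane.pixel_world_coords()
        inside = (coords[..., 0] <= n - 1) & (coords[..., 1] <= n - 1)
        expected = (
            2.0
            + 0.5 * coords[..., 0]
            - 1.5 * coords[..., 1]
            + 0.25 * coords[..., 2]
            + 0.1 * coords[..., 0] * coords[..., 1]
            - 0.2 * coords[..., 1] * coords[..., 2]
        )
        assert oob == int((~inside).sum()) and oob > 0
        assert np.allclose(vx[inside], expected[inside])
        assert np.allclose(vy[inside], 2 * expected[inside])
        assert not vx[~inside].any()
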