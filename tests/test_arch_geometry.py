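"""Arch/wire geometry: arc length, station coordinates, deformation recovery."""

import numpy as np
import pytest
from dataclasses import replace

from orthowire.arch_geometry import (
    ProjectionError,
    WirePath,
    arc_length_coordinate,
    build_deformed_path,
    chord_coordinate,
    generate_arch_curve,
    make_bracket_sites,
    measure_deformation,
    read_wirepath_csv,
    trim_wire,
    write_wirepath_csv,
)
from conftest import random_rotation, straight_path


class TestGenerateArchCurve:
    @pytest.mark.parametrize("length", [152.12, 10.0, 104.09])
    def test_total_length_exact(self, length):
        path = generate_arch_curve(total_length=length)
        assert path.total_length == pytest.approx(length, rel=1e-12)

    def test_semicircular_form_has_pi_r_length(self):
        # width 2r, depth r, flatness 2 is a semicircle: the isotropic scale
        # applied to hit the requested length must then be ~1
        r = 10.0
        path = generate_arch_curve(
            width=2 * r, depth=r, flatness=2.0, total_length=np.pi * r, n_samples=10_000
        )
        halfwidth = path.samples[:, 0].max()
        assert halfwidth == pytest.approx(r, rel=1e-6)

    def test_deterministic(self):
        a = generate_arch_curve(seed=5)
        b = generate_arch_curve(seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)

    @pytest.mark.parametrize(
        "kwargs", [{"total_length": -1.0}, {"n_samples": 8}, {"flatness": 0.5}]
    )
    def test_degenerate_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_arch_curve(**kwargs)

    def test_resample_idempotent(self):
        path = generate_arch_curve(total_length=109.68, n_samples=1501)
        again = path.resample(1501)
        assert again.total_length == pytest.approx(path.total_length, rel=1e-9)
        np.testing.assert_allclose(again.samples, path.samples, atol=1e-12)

    def test_arclength_strictly_increasing(self):
        path = generate_arch_curve()
        assert np.all(np.diff(path.arclength) > 0)


class TestTrimWire:
    @pytest.mark.parametrize(
        "full,target,removed",
        [(152.12, 109.68, 42.44), (143.12, 104.09, 39.03)],
    )
    def test_removed_length_is_difference(self, full, target, removed):
        path = generate_arch_curve(total_length=full)
        trimmed = trim_wire(path, target)
        assert trimmed.total_length == pytest.approx(target, abs=1e-9)
        assert path.total_length - trimmed.total_length == pytest.approx(
            removed, abs=1e-9
        )

    def test_trim_to_own_length_is_identity(self):
        path = generate_arch_curve(total_length=50.0)
        trimmed = trim_wire(path, 50.0)
        assert trimmed.total_length == pytest.approx(50.0, abs=1e-9)

    def test_target_longer_than_wire_rejected(self):
        path = generate_arch_curve(total_length=50.0)
        with pytest.raises(ValueError):
            trim_wire(path, 60.0)

    def test_from_end_mode_keeps_start(self):
        path = generate_arch_curve(total_length=50.0)
        trimmed = trim_wire(path, 30.0, mode="from-end")
        np.testing.assert_allclose(trimmed.samples[0], path.samples[0], atol=1e-12)
        assert trimmed.total_length == pytest.approx(30.0, abs=1e-9)


class TestStationCoordinates:
    def test_endpoints(self, straight_wire):
        assert arc_length_coordinate(straight_wire, straight_wire.samples[0]) == 0.0
        assert arc_length_coordinate(
            straight_wire, straight_wire.samples[-1]
        ) == pytest.approx(straight_wire.total_length)

    def test_straight_midpoint(self):
        path = straight_path(length=10.0, n=2)
        assert arc_length_coordinate(path, [5.0, 0, 0]) == pytest.approx(5.0)
        assert chord_coordinate(path, [5.0, 0, 0]) == pytest.approx(5.0)

    def test_chord_equals_arc_on_straight_path(self, straight_wire):
        for s in [2.0, 7.5, 13.0]:
            p = straight_wire.point_at(s)
            assert chord_coordinate(straight_wire, p) == pytest.approx(
                arc_length_coordinate(straight_wire, p), rel=1e-12
            )

    def test_quarter_circle_closed_form(self):
        r = 12.0
        t = np.linspace(0, np.pi / 2, 20001)
        pts = np.column_stack([r * np.sin(t), r * (1 - np.cos(t)), np.zeros_like(t)])
        path = WirePath(control_points=pts[::2000], samples=pts)
        end = pts[-1]
        assert chord_coordinate(path, end) == pytest.approx(r * np.sqrt(2), rel=1e-6)
        assert arc_length_coordinate(path, end) == pytest.approx(
            np.pi * r / 2, rel=1e-6
        )

    def test_far_point_raises(self, straight_wire):
        with pytest.raises(ProjectionError):
            arc_length_coordinate(straight_wire, [5.0, 3.0, 0.0])

    def test_arc_length_rigid_motion_invariant(self, arch_wire):
        rng = np.random.default_rng(11)
        s_ref = 40.0
        p_ref = arch_wire.point_at(s_ref)
        for _ in range(5):
            R = random_rotation(rng)
            t = rng.uniform(-50, 50, 3)
            moved = replace(arch_wire, samples=arch_wire.samples @ R.T + t)
            assert moved.total_length == pytest.approx(
                arch_wire.total_length, rel=1e-9
            )
            y = arc_length_coordinate(moved, R @ p_ref + t)
            assert y == pytest.approx(s_ref, rel=1e-9)

    def test_chord_never_exceeds_arc(self, arch_wire):
        for s in np.linspace(1.0, arch_wire.total_length - 1.0, 25):
            p = arch_wire.point_at(s)
            z = chord_coordinate(arch_wire, p)
            y = arc_length_coordinate(arch_wire, p)
            assert z <= y + 1e-9


class TestDeformation:
    def _sites(self, wire, n=5):
        fracs = np.linspace(0.1, 0.9, n)
        stations = {f"1.{i+1}": f * wire.total_length for i, f in enumerate(fracs)}
        return make_bracket_sites(wire, stations)

    def test_zero_offsets_identity(self, arch_wire):
        sites = self._sites(arch_wire)
        pair = build_deformed_path(arch_wire, sites, np.zeros((len(sites), 3)))
        for site in sites:
            assert measure_deformation(pair, site) == 0.0

    def test_single_injected_offset_recovered(self, arch_wire):
        sites = self._sites(arch_wire)
        offsets = np.zeros((len(sites), 3))
        offsets[2] = [0.0, 2.75, 0.0]
        pair = build_deformed_path(arch_wire, sites, offsets)
        assert measure_deformation(pair, sites[2]) == pytest.approx(2.75, rel=0.02)

    def test_random_offsets_recovered_within_2_percent(self, arch_wire):
        rng = np.random.default_rng(7)
        sites = self._sites(arch_wire, n=8)
        mags = rng.uniform(1.0, 9.0, len(sites))
        dirs = rng.normal(size=(len(sites), 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pair = build_deformed_path(arch_wire, sites, mags[:, None] * dirs)
        for site, m in zip(sites, mags):
            assert measure_deformation(pair, site) == pytest.approx(m, rel=0.02)

    def test_known_correspondence_distances(self, arch_wire):
        sites = self._sites(arch_wire, n=2)
        pair = build_deformed_path(arch_wire, sites, np.zeros((2, 3)))
        pair.correspondences["1.3"] = (np.zeros(3), np.array([0.0, 0.0, 9.2]))
        pair.correspondences["9.9"] = (np.array([1.0, 2, 3]), np.array([4.0, 6, 3]))
        assert measure_deformation(pair, "1.3") == pytest.approx(9.2)
        assert measure_deformation(pair, "9.9") == pytest.approx(5.0)

    def test_missing_correspondence_raises(self, arch_wire):
        sites = self._sites(arch_wire, n=2)
        pair = build_deformed_path(arch_wire, sites, np.zeros((2, 3)))
        with pytest.raises(KeyError):
            measure_deformation(pair, "4.8")

    def test_collinear_guide_points_rejected(self):
        from orthowire.arch_geometry import BracketSite

        with pytest.raises(ValueError, match="collinear"):
            BracketSite(
                tooth="1.1",
                guide_points=np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float),
            )


def test_wirepath_csv_roundtrip(tmp_path, arch_wire):
    f = tmp_path / "wire.csv"
    write_wirepath_csv(arch_wire, f)
    back = read_wirepath_csv(f)
    np.testing.assert_allclose(back.samples, arch_wire.samples, atol=1e-9)
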