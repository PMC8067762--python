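"""Dump parsing, Voronoi volumes, group stress, and strain extraction."""

import io

import numpy as np
import pytest

from nfvisco import (
    ATM_TO_GPA,
    AtomFrame,
    ConsistencyError,
    FormatError,
    ParameterError,
    group_stress,
    group_stress_series,
    read_dump,
    strain_series,
    voronoi_volumes,
    write_dump,
)

TWO_FRAME_DUMP = """\
ITEM: TIMESTEP
0
ITEM: NUMBER OF ATOMS
4
ITEM: BOX BOUNDS pp pp pp
0.0 10.0
0.0 10.0
0.0 10.0
ITEM: ATOMS id x y z sxx syy szz sxy sxz syz
1 1.0 1.0 1.0 -10 -10 -10 0 0 0
2 9.0 1.0 1.0 -10 -10 -10 0 0 0
3 1.0 9.0 1.0 -10 -10 -10 0 0 0
4 1.0 1.0 9.0 -10 -10 -10 0 0 0
ITEM: TIMESTEP
100
ITEM: NUMBER OF ATOMS
4
ITEM: BOX BOUNDS pp pp pp
0.0 10.0
0.0 10.0
0.0 10.0
ITEM: ATOMS id x y z sxx syy szz sxy sxz syz
4 1.0 1.0 9.5 -20 -20 -20 0 0 0
2 9.0 1.0 1.0 -20 -20 -20 0 0 0
1 1.0 1.0 1.5 -20 -20 -20 0 0 0
3 1.0 9.0 1.0 -20 -20 -20 0 0 0
"""


def _random_frame(seed=11, n=12, edge=25.0):
    rng = np.random.default_rng(seed)
    return AtomFrame(
        timestep=int(rng.integers(0, 10_000)),
        box_bounds=[[0.0, edge]] * 3,
        ids=np.arange(1, n + 1),
        coords=rng.uniform(0.5, edge - 0.5, (n, 3)),
        stress_pv=rng.normal(0.0, 50.0, (n, 6)),
    )


class TestDumpIO:
    def test_fixture_round_trip_two_frames(self):
        frames = read_dump(io.StringIO(TWO_FRAME_DUMP))
        assert len(frames) == 2
        for frame in frames:
            assert frame.n_atoms == 4
            assert frame.ids.tolist() == [1, 2, 3, 4]
        assert frames[1].timestep == 100

    def test_scrambled_atom_order_is_id_sorted(self):
        frames = read_dump(io.StringIO(TWO_FRAME_DUMP))
        # frame 2 is written in order 4,2,1,3; atom 4 has z=9.5
        assert frames[1].ids.tolist() == [1, 2, 3, 4]
        assert frames[1].coords[3, 2] == pytest.approx(9.5)

    def test_writer_reader_round_trip_is_field_identical(self, tmp_path):
        frame = _random_frame(seed=11)
        path = tmp_path / "frame.dump"
        write_dump([frame], path)
        (back,) = read_dump(path)
        assert back.timestep == frame.timestep
        np.testing.assert_array_equal(back.ids, frame.ids)
        np.testing.assert_array_equal(back.coords, frame.coords)
        np.testing.assert_array_equal(back.stress_pv, frame.stress_pv)
        np.testing.assert_array_equal(back.box_bounds, frame.box_bounds)

    def test_missing_stress_columns_named_in_error(self):
        text = TWO_FRAME_DUMP.replace(" syz", "").replace(" 0 0 0\n", " 0 0\n")
        with pytest.raises(FormatError, match="syz"):
            read_dump(io.StringIO(text))

    def test_indexed_stress_column_names_accepted(self):
        text = TWO_FRAME_DUMP.replace(
            "sxx syy szz sxy sxz syz",
            "c_stress[1] c_stress[2] c_stress[3] c_stress[4] c_stress[5] c_stress[6]",
        )
        frames = read_dump(io.StringIO(text))
        assert frames[0].stress_pv[0, 0] == -10.0

    def test_malformed_trailing_frame_warns_and_preserves_prior(self):
        truncated = TWO_FRAME_DUMP.rstrip("\n").rsplit("\n", 2)[0]  # drop 2 atom rows
        with pytest.warns(UserWarning, match="trailing frame"):
            frames = read_dump(io.StringIO(truncated))
        assert len(frames) == 1 and frames[0].timestep == 0

    def test_image_flags_unwrap_coordinates(self):
        text = (
            "ITEM: TIMESTEP\n0\n"
            "ITEM: NUMBER OF ATOMS\n2\n"
            "ITEM: BOX BOUNDS pp pp pp\n0.0 10.0\n0.0 10.0\n0.0 10.0\n"
            "ITEM: ATOMS id x y z sxx syy szz sxy sxz syz ix iy iz\n"
            "1 1.0 2.0 3.0 0 0 0 0 0 0 1 0 0\n"
            "2 4.0 5.0 6.0 0 0 0 0 0 0 0 -2 0\n"
        )
        frames = read_dump(io.StringIO(text))
        # unwrapped coordinate = wrapped + image flag * box length
        assert frames[0].coords[0, 0] == pytest.approx(11.0)
        assert frames[0].coords[1, 1] == pytest.approx(-15.0)


class TestVoronoiVolumes:
    def test_single_atom_gets_whole_box(self):
        frame = AtomFrame(0, [[0, 10]] * 3, [1], [[5.0, 5.0, 5.0]], np.zeros((1, 6)))
        np.testing.assert_allclose(voronoi_volumes(frame), [1000.0])

    def test_simple_cubic_lattice_splits_evenly(self):
        pts = np.array([[x, y, z] for x in (5.0, 15.0) for y in (5.0, 15.0)
                        for z in (5.0, 15.0)])
        frame = AtomFrame(0, [[0, 20]] * 3, np.arange(1, 9), pts, np.zeros((8, 6)))
        np.testing.assert_allclose(voronoi_volumes(frame), np.full(8, 1000.0), rtol=1e-9)

    def test_random_configuration_conserves_box_volume(self):
        rng = np.random.default_rng(5)
        n, edge = 30, 30.0
        frame = AtomFrame(0, [[0, edge]] * 3, np.arange(1, n + 1),
                          rng.uniform(0, edge, (n, 3)), np.zeros((n, 6)))
        vols = voronoi_volumes(frame)
        assert np.all(vols > 0)
        assert vols.sum() == pytest.approx(edge**3, rel=1e-6)

    def test_monte_carlo_nearest_site_cross_check(self):
        # independent estimate: fraction of 1e6 uniform samples nearest to
        # each site (periodic metric) times the box volume, 1% tolerance
        rng = np.random.default_rng(5)
        n, edge = 30, 30.0
        pts = rng.uniform(0, edge, (n, 3))
        frame = AtomFrame(0, [[0, edge]] * 3, np.arange(1, n + 1), pts, np.zeros((n, 6)))
        vols = voronoi_volumes(frame)

        m = 1_000_000
        samples = rng.uniform(0, edge, (m, 3))
        counts = np.zeros(n, dtype=np.int64)
        for chunk in np.array_split(samples, 20):
            delta = chunk[:, None, :] - pts[None, :, :]
            delta -= edge * np.round(delta / edge)  # minimum image
            nearest = np.argmin((delta**2).sum(axis=2), axis=1)
            counts += np.bincount(nearest, minlength=n)
        mc_vols = counts / m * edge**3
        np.testing.assert_allclose(vols, mc_vols, rtol=0.01, atol=0.01 * edge**3 / n)

    def test_coincident_atoms_jittered_with_warning(self):
        pts = np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0], [1.0, 1.0, 1.0]])
        frame = AtomFrame(0, [[0, 10]] * 3, [1, 2, 3], pts, np.zeros((3, 6)))
        with pytest.warns(UserWarning, match="coincident"):
            vols = voronoi_volumes(frame)
        assert vols.sum() == pytest.approx(1000.0, rel=1e-6)

    def test_non_periodic_cells_clip_to_box(self):
        frame = AtomFrame(0, [[0, 10]] * 3, [1, 2],
                          [[2.0, 5.0, 5.0], [8.0, 5.0, 5.0]], np.zeros((2, 6)))
        vols = voronoi_volumes(frame, periodic=False)
        np.testing.assert_allclose(vols, [500.0, 500.0], rtol=1e-9)


class TestGroupStress:
    def test_uniform_pressure_field_recovers_pressure(self):
        frame = _random_frame(seed=2)
        vols = voronoi_volumes(frame)
        p = 5000.0  # atm
        stress_pv = np.zeros((frame.n_atoms, 6))
        stress_pv[:, :3] = -p * vols[:, None]
        frame2 = AtomFrame(frame.timestep, frame.box_bounds, frame.ids,
                           frame.coords, stress_pv)
        tensor = group_stress(frame2, frame2.ids, vols)
        np.testing.assert_allclose(tensor[:3], p * ATM_TO_GPA, rtol=1e-12)
        np.testing.assert_allclose(tensor[3:], 0.0)

    def test_zero_stress_gives_zero_tensor(self):
        frame = _random_frame(seed=3)
        frame = AtomFrame(frame.timestep, frame.box_bounds, frame.ids, frame.coords,
                          np.zeros((frame.n_atoms, 6)))
        vols = voronoi_volumes(frame)
        np.testing.assert_array_equal(group_stress(frame, frame.ids, vols), np.zeros(6))

    def test_matches_brute_force_sum_over_members(self):
        frame = _random_frame(seed=9)
        vols = voronoi_volumes(frame)
        members = frame.ids[::2]
        tensor = group_stress(frame, members, vols)
        mask = np.isin(frame.ids, members)
        expected = -frame.stress_pv[mask].sum(axis=0) / vols[mask].sum() * ATM_TO_GPA
        np.testing.assert_allclose(tensor, expected, rtol=1e-12)

    def test_union_of_disjoint_groups_is_volume_weighted_mean(self):
        frame = _random_frame(seed=4)
        vols = voronoi_volumes(frame)
        a, b = frame.ids[:6], frame.ids[6:]
        sa, sb = group_stress(frame, a, vols), group_stress(frame, b, vols)
        va = vols[np.isin(frame.ids, a)].sum()
        vb = vols[np.isin(frame.ids, b)].sum()
        union = group_stress(frame, frame.ids, vols)
        np.testing.assert_allclose(union, (sa * va + sb * vb) / (va + vb), rtol=1e-10)

    def test_empty_member_set_rejected(self):
        frame = _random_frame()
        with pytest.raises(ParameterError):
            group_stress(frame, [], voronoi_volumes(frame))

    def test_unknown_member_rejected(self):
        frame = _random_frame()
        with pytest.raises(ParameterError, match="999"):
            group_stress(frame, [999], voronoi_volumes(frame))


class TestStrainSeries:
    def _frames_with_displacement(self, displacements, axis=0):
        rng = np.random.default_rng(0)
        base = rng.uniform(5.0, 20.0, (5, 3))
        frames = []
        for k, d in enumerate(displacements):
            coords = base.copy()
            coords[:, axis] += d
            frames.append(AtomFrame(k * 10, [[0, 100]] * 3, np.arange(1, 6), coords,
                                    np.zeros((5, 6))))
        return frames

    def test_eight_angstrom_displacement_over_ten_reference_gives_080(self):
        frames = self._frames_with_displacement([0.0, 8.0])
        series = strain_series(frames, [1, 2, 3, 4, 5], axis="x", reference_length=10.0)
        assert series.strain[-1] == pytest.approx(0.8)

    def test_no_displacement_gives_zero_strain(self):
        frames = self._frames_with_displacement([0.0, 0.0, 0.0])
        series = strain_series(frames, [1, 2, 3], axis="x", reference_length=10.0)
        np.testing.assert_array_equal(series.strain, 0.0)

    def test_linear_ramp_recovers_nominal_rate(self):
        # displacement ramp at nominal rate r (strain/ps) over T ps
        r, ref, dt = 2.5e-3, 12.0, 10.0
        times = np.arange(11) * dt
        frames = self._frames_with_displacement(r * ref * times)
        series = strain_series(frames, [1, 2, 3, 4, 5], axis="x",
                               reference_length=ref, dt=1.0)
        slope = np.polyfit(series.time, series.strain, 1)[0]
        assert slope == pytest.approx(r, rel=1e-6)

    def test_negative_axis_pulling_direction(self):
        frames = self._frames_with_displacement([0.0, -8.0])
        series = strain_series(frames, [1, 2, 3, 4, 5], axis="-x", reference_length=10.0)
        assert series.strain[-1] == pytest.approx(0.8)

    def test_missing_pulled_atom_raises_consistency_error(self):
        frames = self._frames_with_displacement([0.0, 1.0])
        with pytest.raises(ConsistencyError):
            strain_series(frames, [1, 99], axis="x", reference_length=10.0)

    def test_nonpositive_reference_length_rejected(self):
        frames = self._frames_with_displacement([0.0, 1.0])
        with pytest.raises(ParameterError):
            strain_series(frames, [1], axis="x", reference_length=0.0)


def test_group_stress_series_from_dump_fixture():
    frames = read_dump(io.StringIO(TWO_FRAME_DUMP))
    series = group_stress_series(frames, [1, 2, 3, 4], axis="x", dt=0.01)
    assert len(series) == 2
    assert series.time[0] == 0.0 and series.time[1] == pytest.approx(1.0)
    # uniform stress_pv of -10 per atom over the whole 1000 A^3 box
    expected = -4 * (-10.0) / 1000.0 * ATM_TO_GPA
    assert series.axial_stress[0] == pytest.approx(expected, rel=1e-9)
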