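"""Analysis battery against closed forms, Monte-Carlo and brute-force
oracles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oxbilayer as ox
from oxbilayer.exceptions import AnalysisError, TrajectoryError
from oxbilayer.frames import Trajectory
from oxbilayer.metrics import (DensityProfile, area_per_lipid,
                               bilayer_thickness, block_error,
                               density_profile, detect_pore, order_parameter,
                               relative_change, scd_from_cosines,
                               select_phosphorus, select_water,
                               water_density_center)
from oxbilayer.synth import (SyntheticSpec, gen_ar1_series,
                             gen_bilayer_trajectory)
from oxbilayer.builder import make_composition

from conftest import (p_plane_topology, single_frame_traj, stack_topologies,
                      water_topology)


class TestScdFromCosines:
    def test_parallel_and_perpendicular_limits(self):
        assert scd_from_cosines([1.0, 1.0]) == 1.0
        assert scd_from_cosines([0.0]) == -0.5

    def test_isotropic_average_is_zero(self, rng):
        """cos(theta) uniform on the sphere: Monte-Carlo mean of
        (3cos^2-1)/2 is 0 within 3 standard errors."""
        c = rng.uniform(-1.0, 1.0, 1_000_000)
        vals = 1.5 * c ** 2 - 0.5
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(scd_from_cosines(c)) < 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(AnalysisError):
            scd_from_cosines([])
        with pytest.raises(AnalysisError):
            scd_from_cosines([1.2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=50))
    def test_bounds(self, cosines):
        assert -0.5 <= scd_from_cosines(cosines) <= 1.0


class TestOrderParameter:
    def test_all_trans_vertical_chains(self):
        """Rigid chains along z: every C-D is perpendicular, S_CD = -1/2."""
        spec = SyntheticSpec(composition=make_composition(24, n_water=0),
                             tilt_deg=0.0, n_frames=4, seed=1)
        traj, _ = gen_bilayer_trajectory(spec)
        res = order_parameter(traj)
        assert res.mean_scd == pytest.approx(-0.5, abs=1e-6)
        assert all(abs(v + 0.5) < 1e-6 for v in res.per_carbon.values())

    def test_tilted_chains_match_brute_force_and_closed_form(self):
        """30 deg tilt with random azimuth: identical to a direct per-lipid
        loop on the same coordinates, and to -0.5*P2(cos 30) within 3 SE."""
        spec = SyntheticSpec(composition=make_composition(72, n_water=0),
                             tilt_deg=30.0, n_frames=30, seed=2)
        traj, truth = gen_bilayer_trajectory(spec)
        res = order_parameter(traj)

        # brute-force oracle: plain python loops, explicit geometry
        t = ox.build_template("POPC")
        chain = list(t.sn1_chain)
        half = math.radians(109.471) / 2.0
        used = traj.times >= (traj.times[0] + traj.times[-1]) / 2.0
        total, count = 0.0, 0
        from oxbilayer.frames import species_particle_indices
        mat = species_particle_indices(traj.top, "POPC")
        for f in np.flatnonzero(used):
            for row in mat:
                pos = traj.coords[f][row[chain]]
                for k in range(1, len(chain) - 1):
                    a = pos[k - 1] - pos[k]
                    b = pos[k + 1] - pos[k]
                    a /= np.linalg.norm(a)
                    b /= np.linalg.norm(b)
                    u = -(a + b)
                    u /= np.linalg.norm(u)
                    v = np.cross(a, b)
                    v /= np.linalg.norm(v)
                    for d in (u * math.cos(half) + v * math.sin(half),
                              u * math.cos(half) - v * math.sin(half)):
                        total += 1.5 * d[2] ** 2 - 0.5
                        count += 1
        assert res.mean_scd == pytest.approx(total / count, abs=1e-12)

        expected = -0.5 * 0.5 * (3 * math.cos(math.radians(30)) ** 2 - 1)
        se = res.frame_standard_error()
        assert abs(res.mean_scd - expected) < 3 * se

    def test_time_average_idempotent_on_frozen_frame(self):
        spec = SyntheticSpec(composition=make_composition(12, n_water=0),
                             tilt_deg=20.0, n_frames=1, seed=3)
        traj, _ = gen_bilayer_trajectory(spec)
        ten = Trajectory(traj.top, 100.0 * (np.arange(10) + 1),
                         np.repeat(traj.boxes, 10, axis=0),
                         np.repeat(traj.coords, 10, axis=0))
        r1 = order_parameter(traj, equil_time=-1.0)
        r10 = order_parameter(ten, equil_time=-1.0)
        assert r10.mean_scd == pytest.approx(r1.mean_scd, abs=1e-12)

    def test_include_c2_switch(self):
        spec = SyntheticSpec(composition=make_composition(12, n_water=0),
                             tilt_deg=10.0, n_frames=2, seed=4)
        traj, _ = gen_bilayer_trajectory(spec)
        with_c2 = order_parameter(traj, include_c2=True)
        without = order_parameter(traj, include_c2=False)
        assert 2 in with_c2.per_carbon
        assert 2 not in without.per_carbon
        assert len(without.per_carbon) == len(with_c2.per_carbon) - 1

    def test_translation_and_relabel_invariance(self):
        spec = SyntheticSpec(composition=make_composition(12, n_water=100),
                             tilt_deg=25.0, n_frames=4, seed=5)
        traj, _ = gen_bilayer_trajectory(spec)
        base = order_parameter(traj).mean_scd
        shifted = Trajectory(traj.top, traj.times, traj.boxes,
                             traj.coords + np.array([1.0, -2.0, 0.7]))
        assert order_parameter(shifted).mean_scd == pytest.approx(base,
                                                                  abs=1e-12)
        relabeled = Trajectory(
            ox.Topology(traj.top.names, traj.top.resnames, traj.top.resids,
                        np.where(traj.top.lipid_ids >= 0,
                                 1000 - traj.top.lipid_ids,
                                 traj.top.lipid_ids),
                        traj.top.elements, traj.top.masses),
            traj.times, traj.boxes, traj.coords)
        assert order_parameter(relabeled).mean_scd == pytest.approx(base,
                                                                    abs=1e-12)

    def test_no_sn1_lipids_rejected(self):
        top = water_topology(10)
        traj = single_frame_traj(top, np.zeros((10, 3)))
        with pytest.raises(AnalysisError, match="sn-1"):
            order_parameter(traj, equil_time=-1.0)


class TestAreaPerLipid:
    def test_constant_box_arithmetic(self):
        top = p_plane_topology(2)
        coords = np.zeros((3, 2, 3))
        traj = Trajectory(top, [100.0, 200.0, 300.0],
                          np.tile([6.0, 6.0, 10.0], (3, 1)), coords)
        r = area_per_lipid(traj, n_per_leaflet=36, equil_time=-1.0)
        assert r.value == pytest.approx(1.0)  # 36 nm^2 / 36 = 1 nm^2 = 100 A^2
        assert r.error == 0.0

    def test_alternating_areas_mean(self):
        top = p_plane_topology(1)
        n = 20
        lx = np.sqrt(np.where(np.arange(n) % 2 == 0, 35.0, 37.0))
        boxes = np.column_stack([lx, lx, np.full(n, 10.0)])
        traj = Trajectory(top, 100.0 * (np.arange(n) + 1), boxes,
                          np.zeros((n, 1, 3)))
        r = area_per_lipid(traj, n_per_leaflet=36, equil_time=-1.0)
        assert r.value * 100 == pytest.approx(100.0)  # A^2

    def test_ar1_error_matches_closed_form(self):
        """Block error of an AR(1) area series within 15% of the analytic
        standard error of a correlated mean."""
        n, phi, sigma = 20000, 0.8, 0.3
        areas = gen_ar1_series(n, 36.0, sigma, phi, seed=77)
        lx = np.sqrt(areas)
        top = p_plane_topology(1)
        traj = Trajectory(top, 100.0 * (np.arange(n) + 1),
                          np.column_stack([lx, lx, np.full(n, 10.0)]),
                          np.zeros((n, 1, 3)))
        r = area_per_lipid(traj, n_per_leaflet=36, equil_time=-1.0)
        expected = sigma / 36.0 / math.sqrt(n) * math.sqrt((1 + phi) / (1 - phi))
        assert r.error == pytest.approx(expected, rel=0.15)

    def test_mean_area_identity(self):
        """APL x n_per_leaflet reproduces the time-mean box area exactly."""
        spec = SyntheticSpec(composition=make_composition(24, n_water=0),
                             n_frames=16, seed=6)
        traj, truth = gen_bilayer_trajectory(spec)
        r = area_per_lipid(traj, n_per_leaflet=12, equil_time=-1.0)
        assert r.value * 12 == pytest.approx(
            np.mean(traj.boxes[:, 0] * traj.boxes[:, 1]), rel=1e-14)

    def test_no_frames_after_equilibration(self):
        top = p_plane_topology(1)
        traj = single_frame_traj(top, np.zeros((1, 3)), time=100.0)
        with pytest.raises(TrajectoryError):
            area_per_lipid(traj, 36, equil_time=200.0)


class TestDensityProfile:
    def test_uniform_water_is_flat(self, rng):
        """Uniformly random waters: every bin within 5% of mass/volume."""
        n_mol, n_frames, box = 60000, 8, (4.0, 4.0, 8.0)
        top = water_topology(n_mol)
        coords = rng.uniform(0, 1, (n_frames, n_mol, 3)) * np.array(box)
        traj = Trajectory(top, 100.0 * (np.arange(n_frames) + 1),
                          np.tile(box, (n_frames, 1)), coords)
        with pytest.warns(UserWarning, match="no phosphorus"):
            prof = density_profile(traj, select_water, equil_time=-1.0)
        expected = n_mol * 18.015 / (box[0] * box[1] * box[2]) * 1.66053907
        assert np.all(np.abs(prof.density / expected - 1.0) < 0.05)

    def test_point_mass_single_bin(self):
        top = stack_topologies(p_plane_topology(2), water_topology(5))
        coords = np.zeros((7, 3))
        coords[0, 2] = 6.9  # P planes define the midplane at z = 5
        coords[1, 2] = 3.1
        coords[2:, 2] = 5.95  # all waters at one z
        traj = single_frame_traj(top, coords, box=(6.0, 6.0, 10.0))
        prof = density_profile(traj, select_water, equil_time=-1.0)
        assert (prof.density > 0).sum() == 1
        peak_z = prof.bin_centers[np.argmax(prof.density)]
        assert peak_z == pytest.approx(0.95, abs=prof.bin_width)

    def test_mass_conservation_invariant(self):
        spec = SyntheticSpec(composition=make_composition(24, n_water=500),
                             n_frames=6, seed=8, area_rel_sigma=0.02)
        traj, _ = gen_bilayer_trajectory(spec)
        for sel in (select_water, select_phosphorus):
            prof = density_profile(traj, sel)
            assert prof.mass_conservation_error() < 1e-3

    def test_empty_selection_warns_and_zeroes(self):
        spec = SyntheticSpec(composition=make_composition(12, n_water=10),
                             n_frames=2, seed=9)
        traj, _ = gen_bilayer_trajectory(spec)
        with pytest.warns(UserWarning, match="empty selection"):
            prof = density_profile(traj, np.zeros(traj.top.n_particles,
                                                  dtype=bool))
        assert not prof.density.any()


class TestThickness:
    def _profile(self, density, lz=10.0):
        n = len(density)
        centers = (np.arange(n) + 0.5) * lz / n - lz / 2.0
        return DensityProfile(n, centers, np.asarray(density, dtype=float),
                              lz / n, 30.0, float(np.sum(density)))

    def test_point_peaks(self):
        # 50 bins over 10 nm put bin centers exactly at +/- 1.9 nm
        lz, n = 10.0, 50
        centers = (np.arange(n) + 0.5) * lz / n - lz / 2.0
        d = np.zeros(n)
        d[np.flatnonzero(np.isclose(centers, -1.9))] = 5.0
        d[np.flatnonzero(np.isclose(centers, 1.9))] = 5.0
        prof = DensityProfile(n, centers, d, lz / n, 30.0, 10.0)
        r = bilayer_thickness(prof)
        assert r.value == pytest.approx(3.8, abs=1e-12)
        assert r.error == pytest.approx(0.2)  # one bin width
        assert r.method == "bin-width"

    def test_gaussian_peaks_recovered_within_bin(self, rng):
        for d_true in rng.uniform(3.0, 4.5, 5):
            centers = (np.arange(100) + 0.5) * 0.1 - 5.0
            dens = (np.exp(-0.5 * ((centers - d_true / 2) / 0.2) ** 2)
                    + np.exp(-0.5 * ((centers + d_true / 2) / 0.2) ** 2))
            prof = DensityProfile(100, centers, dens, 0.1, 30.0, 1.0)
            r = bilayer_thickness(prof)
            assert abs(r.value - d_true) <= 0.1

    def test_mirror_symmetry(self):
        d = np.zeros(100)
        d[30] = d[69] = 2.0
        r1 = bilayer_thickness(self._profile(d))
        r2 = bilayer_thickness(self._profile(d[::-1]))
        assert r1.value == pytest.approx(r2.value)

    def test_merged_leaflets_flagged(self):
        d = np.zeros(100)
        d[50] = 1.0  # single central peak: no lower-side signal
        with pytest.raises(AnalysisError, match="peak"):
            bilayer_thickness(self._profile(d))


class TestWaterDensityCenter:
    def test_dry_core_is_zero(self):
        spec = SyntheticSpec(composition=make_composition(24, n_water=400),
                             n_frames=4, seed=10)
        traj, _ = gen_bilayer_trajectory(spec)
        assert water_density_center(traj).value == 0.0

    def test_full_water_box_counting_oracle(self):
        """No lipids: the core slab density equals the overall generated
        water density within 2%."""
        comp = make_composition(0, n_water=4000, box=(5.0, 5.0, 8.0))
        spec = SyntheticSpec(composition=comp, n_frames=4, seed=11,
                             area_rel_sigma=0.0)
        traj, _ = gen_bilayer_trajectory(spec)
        n_placed = int(traj.top.is_water_oxygen.sum())
        expected = n_placed * 18.015 / (5.0 * 5.0 * 8.0) * 1.66053907
        with pytest.warns(UserWarning, match="no phosphorus"):
            got = water_density_center(traj).value
        assert got == pytest.approx(expected, rel=0.02)

    def test_cylinder_geometric_oracle(self):
        """Inserted bulk-packed column: slab density ~ rho * pi r^2 / A."""
        spec = SyntheticSpec(composition=make_composition(72, n_water=1000),
                             pore_radius=7.5, n_frames=30, seed=12)
        traj, truth = gen_bilayer_trajectory(spec)
        got = water_density_center(traj).value
        assert got == pytest.approx(truth.water_core_density, rel=0.10)


class TestDetectPore:
    def test_generator_pore_recovered(self):
        spec = SyntheticSpec(composition=make_composition(72, n_water=1000),
                             pore_radius=7.5, n_frames=60, seed=13)
        traj, truth = gen_bilayer_trajectory(spec)
        rep = detect_pore(traj)
        assert rep.spanning is True
        assert rep.diameter_max == pytest.approx(15.0, abs=2.0)
        assert rep.diameter_min <= rep.diameter_max
        assert rep.frame_of_onset is not None

    def test_dry_core_not_spanning(self):
        spec = SyntheticSpec(composition=make_composition(36, n_water=600),
                             n_frames=8, seed=14)
        traj, _ = gen_bilayer_trajectory(spec)
        assert detect_pore(traj).spanning is False

    def test_disjoint_half_channels_not_spanning(self):
        """Two water stubs approaching from both sides but separated at the
        midplane do not form a pore."""
        n_half = 40
        top = stack_topologies(p_plane_topology(4),
                               water_topology(2 * n_half))
        rng = np.random.default_rng(0)
        coords = np.zeros((4 + 2 * n_half, 3))
        coords[:2] = [3.0, 3.0, 6.9]
        coords[2:4] = [3.0, 3.0, 3.1]  # P planes -> z_mid = 5, peaks +-1.9
        zu = np.linspace(5.55, 6.85, n_half)
        zl = np.linspace(3.15, 4.45, n_half)
        coords[4:4 + n_half] = np.column_stack(
            [np.full(n_half, 3.0) + rng.normal(0, 0.02, n_half),
             np.full(n_half, 3.0), zu])
        coords[4 + n_half:] = np.column_stack(
            [np.full(n_half, 3.0) + rng.normal(0, 0.02, n_half),
             np.full(n_half, 3.0), zl])
        traj = single_frame_traj(top, coords, box=(6.0, 6.0, 10.0))
        rep = detect_pore(traj, equil_time=-1.0)
        assert rep.spanning is False
        assert rep.diameter_max is None

    def test_unresolvable_span(self):
        top = water_topology(20)
        coords = np.random.default_rng(1).uniform(0, 6, (20, 3))
        traj = single_frame_traj(top, coords, box=(6.0, 6.0, 10.0))
        with pytest.warns(UserWarning, match="empty selection"):
            rep = detect_pore(traj, equil_time=-1.0)
        assert rep.spanning is None


class TestBlockError:
    def test_iid_matches_naive_standard_error(self):
        x = gen_ar1_series(10_000, 0.0, 1.0, 0.0, seed=11)
        assert block_error(x).error == pytest.approx(0.01, rel=0.10)

    def test_ar1_matches_correlated_closed_form(self):
        x = gen_ar1_series(100_000, 5.0, 1.0, 0.9, seed=12)
        expected = 1.0 / math.sqrt(100_000) * math.sqrt(1.9 / 0.1)
        assert block_error(x).error == pytest.approx(expected, rel=0.15)

    def test_positively_correlated_exceeds_naive(self):
        x = gen_ar1_series(50_000, 0.0, 1.0, 0.7, seed=13)
        naive = x.std(ddof=1) / math.sqrt(len(x))
        assert block_error(x).error > naive

    def test_constant_series(self):
        assert block_error(np.full(64, 3.14)).error == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(AnalysisError):
            block_error(np.arange(10))


class TestRelativeChange:
    @pytest.mark.parametrize("value,ref,expected",
                             [(110, 100, 10.0), (100, 100, 0.0),
                              (90, 100, -10.0)])
    def test_percent_change(self, value, ref, expected):
        assert relative_change(value, ref) == pytest.approx(expected)

    def test_zero_reference(self):
        with pytest.raises(AnalysisError):
            relative_change(1.0, 0.0)
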