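"""Observable computations checked against constructed and synthetic data."""

import math

import numpy as np
import pandas as pd
import pytest

import regucharge as rc
from regucharge.fixtures import MixtureFixtureSpec, generate_mixture_trajectory
from regucharge.observables import (distance_resolved_ionization,
                                    min_distance_to_polyanion,
                                    molecule_frame_table, unwrap_molecule)
from regucharge.system_model import InvalidArgumentError
from regucharge.trajectory import Trajectory
from regucharge.system_model import (POLYANION, OLIGOCATION, _assemble_meta,
                                     build_topology, default_bead_specs)


def _tiny_system(L=10.0):
    """One 1-monomer polyanion + one 1-monomer oligocation, positions settable."""
    specs = default_bead_specs()
    pa = build_topology(POLYANION, 1, (specs["pa_backbone"], specs["pa_side"]))
    oc = build_topology(OLIGOCATION, 1, (specs["oc_backbone"], specs["oc_side"]))
    meta = _assemble_meta([pa, oc], [])
    pos = np.zeros((4, 3))
    return meta, pos, L


def _traj_from(meta, frames_pos, L, ionization=None):
    F = len(frames_pos)
    tit = meta.titratable_beads
    ion = np.zeros((F, tit.size), np.int8) if ionization is None else np.asarray(ionization, np.int8)
    q = np.zeros((F, meta.n_beads), np.float32)
    for f in range(F):
        qq = meta.valence.astype(np.float32)
        qq[tit] *= ion[f]
        q[f] = qq
    scalars = pd.DataFrame({"cycle": np.arange(F)})
    return Trajectory(meta=meta, box_length=L, positions=np.asarray(frames_pos, float),
                      charges=q, ionization=ion, scalars=scalars, info={})


class TestDegreeOfIonization:
    def test_single_frame_mean(self):
        a, _ = rc.degree_of_ionization([[1, 1, 0, 0]])
        assert a == 0.5

    def test_mean_over_frames(self):
        a, _ = rc.degree_of_ionization([[1, 1], [0, 0]])
        assert a == 0.5

    def test_bernoulli_law_of_large_numbers(self):
        rng = np.random.default_rng(0)
        frames = (rng.random((10_000, 1)) < 0.3).astype(int)
        a, se = rc.degree_of_ionization(frames)
        assert a == pytest.approx(0.30, abs=0.01)
        assert 0 < se < 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rc.degree_of_ionization(np.zeros((0, 4)))


class TestMinDistance:
    def test_direct_distance(self):
        meta, pos, L = _tiny_system()
        pos[0] = pos[1] = [1.0, 0.0, 0.0]     # polyanion beads
        pos[2] = pos[3] = [0.0, 0.0, 0.0]     # oligocation COM at origin
        assert min_distance_to_polyanion(pos, meta, L, 1) == pytest.approx(1.0)

    def test_minimum_image_wrap(self):
        meta, pos, L = _tiny_system(L=10.0)
        pos[0] = pos[1] = [9.5, 0.0, 0.0]
        pos[2] = pos[3] = [0.5, 0.0, 0.0]
        assert min_distance_to_polyanion(pos, meta, L, 1) == pytest.approx(1.0)

    def test_coincident_is_zero(self):
        meta, pos, L = _tiny_system()
        assert min_distance_to_polyanion(pos, meta, L, 1) == pytest.approx(0.0)

    def test_no_polyanion_rejected(self):
        specs = default_bead_specs()
        oc = build_topology(OLIGOCATION, 1, (specs["oc_backbone"], specs["oc_side"]))
        meta = _assemble_meta([oc], [])
        with pytest.raises(InvalidArgumentError):
            min_distance_to_polyanion(np.zeros((2, 3)), meta, 10.0, 0)


class TestCondensedFraction:
    def test_all_near_gives_one_all_far_gives_zero(self):
        meta, pos, L = _tiny_system()
        pos[0] = pos[1] = [5.0, 5.0, 5.0]
        near = pos.copy()
        near[2] = near[3] = [5.0, 6.0, 5.0]
        far = pos.copy()
        far[2] = far[3] = [5.0, 0.0, 5.0]
        t_near = _traj_from(meta, [near] * 3, L)
        t_far = _traj_from(meta, [far] * 3, L)
        assert rc.condensed_fraction(t_near).fraction == 1.0
        assert rc.condensed_fraction(t_far).fraction == 0.0

    def test_fixture_fraction_recovered(self):
        spec = MixtureFixtureSpec(n_molecules=20, n_frames=500,
                                  condensed_fraction=0.3, seed=5)
        traj = generate_mixture_trajectory(spec)
        res = rc.condensed_fraction(traj)
        assert res.fraction == pytest.approx(0.30, abs=0.01)   # binomial s.e. ~ 0.005

    def test_monotone_in_threshold(self):
        spec = MixtureFixtureSpec(n_molecules=10, n_frames=100, seed=1)
        traj = generate_mixture_trajectory(spec)
        tab = molecule_frame_table(traj)
        fracs = [rc.condensed_fraction(traj, threshold=t, table=tab).fraction
                 for t in (0.5, 1.0, 2.0, 5.0, 9.0)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))


@pytest.fixture(scope="module")
def mixture():
    spec = MixtureFixtureSpec(n_molecules=24, n_frames=400,
                              condensed_fraction=0.4,
                              alpha_condensed=0.95, alpha_free=0.05,
                              sites_per_molecule=4, seed=9)
    return generate_mixture_trajectory(spec)


class TestDistanceResolvedIonization:

    def test_bimodal_alpha_levels_recovered(self, mixture):
        profile, scatter = distance_resolved_ionization(mixture)
        near = profile[(profile.bin_right <= 1.5) & (profile.population > 0)]
        far = profile[(profile.bin_left >= 8.0) & (profile.population > 0)]
        assert near.population.sum() > 0 and far.population.sum() > 0
        a_near = (near.mean_alpha * near.population).sum() / near.population.sum()
        a_far = (far.mean_alpha * far.population).sum() / far.population.sum()
        assert a_near == pytest.approx(0.95, abs=0.02)
        assert a_far == pytest.approx(0.05, abs=0.02)
        # population gap between the two clusters
        gap = profile[(profile.bin_left >= 2.0) & (profile.bin_right <= 8.0)]
        assert gap.population.sum() == 0

    def test_population_weighted_alpha_matches_global(self, mixture):
        profile, _ = distance_resolved_ionization(mixture)
        occ = profile[profile.population > 0]
        weighted = (occ.mean_alpha * occ.population).sum() / occ.population.sum()
        global_alpha, _ = rc.degree_of_ionization(mixture.ionization)
        assert weighted == pytest.approx(global_alpha, abs=1e-12)

    def test_scatter_has_one_row_per_molecule_frame(self, mixture):
        _, scatter = distance_resolved_ionization(mixture)
        assert len(scatter) == 24 * 400


class TestEndToEnd:
    def _rod_traj(self, n_frames=2):
        specs = default_bead_specs()
        pa = build_topology(POLYANION, 48, (specs["pa_backbone"], specs["pa_side"]))
        meta = _assemble_meta([pa], [])
        pos = np.zeros((96, 3))
        for i in range(48):
            pos[2 * i] = [1.0 + 0.4 * i, 10.0, 10.0]
            pos[2 * i + 1] = pos[2 * i] + [0.0, 0.4, 0.0]
        return _traj_from(meta, [pos] * n_frames, L=40.0)

    def test_straight_rod_contour(self):
        mean, se = rc.end_to_end(self._rod_traj())
        assert mean == pytest.approx(47 * 0.4)
        assert se == pytest.approx(0.0, abs=1e-12)    # frozen conformation

    def test_unwrapping_across_periodic_boundary(self):
        traj = self._rod_traj()
        traj.positions %= 8.0
        traj.box_length = 8.0
        mean, _ = rc.end_to_end(traj)
        assert mean == pytest.approx(47 * 0.4)

    def test_ideal_chain_statistics(self):
        """Random-walk backbone: <R^2> ~ N b^2 within 10%."""
        specs = default_bead_specs()
        N, b = 40, 0.4
        pa = build_topology(POLYANION, N, (specs["pa_backbone"], specs["pa_side"]))
        meta = _assemble_meta([pa], [])
        rng = np.random.default_rng(2)
        frames = []
        for _ in range(1000):
            steps = rng.normal(size=(N - 1, 3))
            steps *= b / np.linalg.norm(steps, axis=1)[:, None]
            bb = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)]) + 50.0
            pos = np.empty((2 * N, 3))
            pos[0::2] = bb
            pos[1::2] = bb
            frames.append(pos)
        traj = _traj_from(meta, frames, L=100.0)
        tab = molecule_frame_table  # noqa: F841  (unused here)
        vals = []
        for f in range(traj.n_frames):
            beads = meta.molecule_beads(0)
            unw = unwrap_molecule(traj.positions[f], beads, meta.bonds, traj.box_length)
            vals.append(((unw[-2] - unw[0]) ** 2).sum())
        assert np.mean(vals) == pytest.approx((N - 1) * b ** 2, rel=0.10)

    def test_single_bead_chain_rejected(self):
        specs = default_bead_specs()
        pa = build_topology(POLYANION, 1, (specs["pa_backbone"], specs["pa_side"]))
        meta = _assemble_meta([pa], [])
        traj = _traj_from(meta, [np.zeros((2, 3))], L=10.0)
        with pytest.raises(InvalidArgumentError):
            rc.end_to_end(traj)


class TestLocalHplusProfile:
    def test_zero_potential_recovers_bulk_ph(self):
        meta, pos, L = _tiny_system()
        traj = _traj_from(meta, [pos], L)
        traj.charges[:] = 0.0    # no charges -> psi = 0 everywhere
        prof = rc.local_hplus_profile(traj, bulk_pH=10.0, kappa=0.3)
        occupied = prof.dropna()
        assert np.allclose(occupied.local_pH, 10.0, atol=1e-9)

    def test_single_charge_screened_profile(self):
        """c_H(r)/c_bulk follows exp(+lambda_B e^(-kappa r)/r) around one -1 charge."""
        meta, pos, L = _tiny_system(L=30.0)
        pos[:] = 15.0   # polyanion (backbone+side) and oligocation all at centre
        traj = _traj_from(meta, [pos], L)
        traj.charges[:] = 0.0
        traj.charges[0, 1] = -1.0   # single polyanion side charge
        kappa, lb = 0.33, 0.71
        prof = rc.local_hplus_profile(traj, bulk_pH=10.0, kappa=kappa,
                                      bjerrum_length=lb, n_probes=4000, seed=1)
        occ = prof.dropna()
        r_mid = 0.5 * (occ.bin_left + occ.bin_right)
        expected = 10.0 ** (-10.0) * np.exp(lb * np.exp(-kappa * r_mid) / r_mid)
        sel = (r_mid > 1.0) & (r_mid < 6.0)
        assert np.allclose(occ.c_h_molar[sel], expected[sel], rtol=0.25)
        # far field: back to bulk within 1%
        far = occ[occ.bin_left > 5.0 / kappa]
        assert np.allclose(far.c_h_molar, 1e-10, rtol=0.01)
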