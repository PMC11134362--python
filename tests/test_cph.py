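"""Constant-pH move mechanics, ideal-limit statistics, and oracle agreement."""

import math

import numpy as np
import pytest
from scipy import stats

import regucharge as rc
from regucharge.system_model import InvalidArgumentError
from regucharge.theory import exact_titration
from regucharge.units import LN10

from conftest import hh_alpha, single_oligocation_state


class TestAcceptanceProbability:
    @pytest.mark.parametrize("du,xi,ph,pka,expected", [
        (0.0, +1, 10.68, 10.68, 1.0),          # exponent 0
        (0.0, +1, 11.68, 10.68, 1.0),          # min with 10
        (0.0, -1, 11.68, 10.68, 0.1),          # 10^-1
        (LN10, +1, 11.68, 10.68, 1.0),         # energy exactly compensated
        (2.0, +1, 10.68, 10.68, math.exp(-2.0)),
    ])
    def test_metropolis_factor(self, du, xi, ph, pka, expected):
        assert rc.acceptance_probability(du, xi, ph, pka) == pytest.approx(expected)

    def test_nonfinite_energy_rejects(self):
        assert rc.acceptance_probability(float("inf"), +1, 12.0, 10.68) == 0.0


class TestProposeMove:
    def test_deprotonation_inserts_cation(self, dh_ff):
        st, _ = single_oligocation_state(2, pH=8.0, ff=dh_ff, seed=0)
        site = int(np.flatnonzero(st.ionization == 1)[0])
        trial, xi = rc.propose_move(st, site)
        assert xi == +1
        assert trial.ionization[site] == 0
        assert trial.implicit_cation_count == st.implicit_cation_count + 1
        assert trial.total_charge() == pytest.approx(0.0)

    def test_protonation_deletes_cation(self, dh_ff):
        st, _ = single_oligocation_state(2, pH=13.0, ff=dh_ff, seed=1)
        site = int(np.flatnonzero(st.ionization == 0)[0])
        trial, xi = rc.propose_move(st, site)
        assert xi == -1
        assert trial.ionization[site] == 1
        assert trial.implicit_cation_count == st.implicit_cation_count - 1
        assert trial.total_charge() == pytest.approx(0.0)

    def test_protonation_without_deletable_cation_is_auto_rejected(self, dh_ff):
        st, _ = single_oligocation_state(2, pH=13.0, ff=dh_ff, seed=1)
        st.implicit_cation_count = 0
        st.implicit_anion_count = int(st.bead_charges().sum())
        site = int(np.flatnonzero(st.ionization == 0)[0])
        trial, xi = rc.propose_move(st, site)
        assert trial is None and xi == -1

    def test_invalid_site_rejected(self, dh_ff):
        st, _ = single_oligocation_state(2, pH=10.0, ff=dh_ff)
        with pytest.raises(InvalidArgumentError):
            rc.propose_move(st, 99)


class TestIdealLimit:
    def test_single_site_stationary_distribution_is_hh_bernoulli(self, ideal_ff):
        """Detailed balance: 1-site ideal system follows the HH Bernoulli law."""
        for dpH in (-1.0, 0.0, 1.0):
            pH = 10.68 + dpH
            st, rng = single_oligocation_state(1, pH=pH, ff=ideal_ff, seed=4)
            cph = rc.CpHParams(pH=pH, moves_per_cycle=1, ld_steps_per_cycle=0,
                               translation_moves=False, seed=4)
            traj = rc.run_cph_ld(st, ideal_ff, rc.IntegratorParams(), cph,
                                 n_cycles=6000, warmup_cycles=500, rng=rng)
            k = int(traj.ionization.sum())
            n = traj.ionization.size
            p = hh_alpha(pH)
            chi = stats.chisquare([k, n - k], [n * p, n * (1 - p)])
            assert chi.pvalue > 1e-3

    def test_ideal_alpha_independent_of_chain_length(self, ideal_ff):
        """With interactions off, alpha(pH) does not depend on n."""
        pH = 10.68 + 0.5
        alphas = {}
        for n in (2, 8):
            st, rng = single_oligocation_state(n, pH=pH, ff=ideal_ff, seed=6)
            cph = rc.CpHParams(pH=pH, ld_steps_per_cycle=5, seed=6)
            traj = rc.run_cph_ld(st, ideal_ff, rc.IntegratorParams(), cph,
                                 n_cycles=4000, warmup_cycles=500, rng=rng)
            alphas[n] = rc.degree_of_ionization(traj.ionization)
        a2, se2 = alphas[2]
        a8, se8 = alphas[8]
        tol = 3 * math.hypot(se2, se8)
        assert abs(a2 - a8) <= max(tol, 0.02)
        assert a2 == pytest.approx(hh_alpha(pH), abs=max(3 * se2, 0.02))


class TestOracleAgreement:
    def test_two_site_toy_matches_enumeration(self, dh_ff):
        """Frozen 2-site system vs exact 4-microstate enumeration."""
        st, rng = single_oligocation_state(2, pH=10.68, ff=dh_ff, seed=7)
        cph = rc.CpHParams(pH=10.68, ld_steps_per_cycle=0,
                           translation_moves=False, seed=7)
        traj = rc.run_cph_ld(st, dh_ff, rc.IntegratorParams(), cph,
                             n_cycles=8000, warmup_cycles=500, rng=rng)
        alpha, se = rc.degree_of_ionization(traj.ionization)

        tit = st.meta.titratable_beads
        L = st.box_length
        rcut = dh_ff.dh_cutoff(L)
        d = st.positions[tit[0]] - st.positions[tit[1]]
        d -= L * np.round(d / L)
        r = float(np.linalg.norm(d))
        # same truncated-shifted pair law the sampler uses
        u = dh_ff.bjerrum_length * (math.exp(-dh_ff.kappa * r) / r
                                    - math.exp(-dh_ff.kappa * rcut) / rcut)
        pair = np.array([[0.0, u], [u, 0.0]])
        exact = exact_titration(2, pair, 10.68, 10.68)
        assert alpha == pytest.approx(exact, abs=max(3 * se, 0.01))


class TestRunContract:
    def test_rejects_warmup_not_less_than_cycles(self, ideal_ff):
        st, rng = single_oligocation_state(2, pH=10.0, ff=ideal_ff)
        with pytest.raises(InvalidArgumentError):
            rc.run_cph_ld(st, ideal_ff, rc.IntegratorParams(),
                          rc.CpHParams(pH=10.0), n_cycles=10, warmup_cycles=10)

    def test_run_is_bitwise_reproducible_at_fixed_seed(self, dh_ff):
        outs = []
        for _ in range(2):
            st, rng = single_oligocation_state(4, pH=10.5, ff=dh_ff, seed=11)
            cph = rc.CpHParams(pH=10.5, ld_steps_per_cycle=20, seed=11)
            traj = rc.run_cph_ld(st, dh_ff, rc.IntegratorParams(), cph,
                                 n_cycles=60, warmup_cycles=10, rng=rng)
            outs.append(traj)
        assert np.array_equal(outs[0].positions, outs[1].positions)
        assert np.array_equal(outs[0].ionization, outs[1].ionization)

    def test_frames_and_scalars_recorded_after_warmup(self, ideal_ff):
        st, rng = single_oligocation_state(2, pH=10.0, ff=ideal_ff, seed=2)
        cph = rc.CpHParams(pH=10.0, ld_steps_per_cycle=2, seed=2)
        traj = rc.run_cph_ld(st, ideal_ff, rc.IntegratorParams(), cph,
                             n_cycles=50, warmup_cycles=20, rng=rng)
        assert traj.n_frames == 30
        assert set(traj.scalars.columns) >= {"cycle", "alpha", "energy", "acceptance"}
        assert traj.scalars["cycle"].iloc[0] == 20


@pytest.fixture(scope="module")
def small_explicit():
    ff = rc.ForceField(electrostatics_mode="coulomb_explicit_ions",
                       ewald_accuracy=1e-4)
    comp = rc.SystemComposition(
        polyanion_length=8, oligocation_length=4, monomer_ratio=(1, 2),
        ionic_strength=5e-4, pH=10.0, box_length=8.0, seed=3,
    )
    rng = np.random.default_rng(3)
    return rc.build_system(comp, ff, rng=rng), ff


class TestExplicitIonMode:

    def test_build_is_electroneutral_with_explicit_ions(self, small_explicit):
        st, ff = small_explicit
        assert st.meta.is_ion.any()
        assert st.total_charge() == pytest.approx(0.0)

    def test_moves_toggle_explicit_ions(self, small_explicit):
        st, ff = small_explicit
        rng = np.random.default_rng(0)
        n_active = int(st.ion_active.sum())
        site = int(np.flatnonzero(st.ionization == 1)[0])
        trial, xi = rc.propose_move(st, site, rng=rng)
        assert xi == +1
        assert int(trial.ion_active.sum()) == n_active + 1
        assert trial.total_charge() == pytest.approx(0.0)

    def test_ionization_enhanced_near_polyanion_in_both_modes(self):
        """Condensation mechanism: a frozen oligocation titrates higher at
        contact with the polyanion than far from it, in DH and Ewald modes."""
        results = {}
        pH = 10.68   # at pKa the electrostatic enhancement of alpha is maximal
        for mode in ("debye_hueckel_implicit_ions", "coulomb_explicit_ions"):
            for placement in ("near", "far"):
                ff = rc.ForceField.from_ionic_strength(
                    5e-4, electrostatics_mode=mode, ewald_accuracy=1e-4)
                comp = rc.SystemComposition(
                    polyanion_length=8, oligocation_length=4, monomer_ratio=(1, 2),
                    ionic_strength=5e-4, pH=pH, box_length=8.0, seed=3,
                )
                rng = np.random.default_rng(3)
                st = rc.build_system(comp, ff, rng=rng)
                # lay the oligocation as a rod parallel to the polyanion,
                # side chains pointing at the chain (contact geometry)
                oc = st.meta.molecule_beads(int(st.meta.oligocation_mol_ids[0]))
                pa_bb = np.flatnonzero(st.meta.polyanion_bead_mask & st.meta.backbone)
                y_off = 1.15 if placement == "near" else 3.9
                for k in range(4):
                    anchor = st.positions[pa_bb[2 + k]]
                    st.positions[oc[2 * k]] = anchor + [0.0, y_off, 0.0]
                    st.positions[oc[2 * k + 1]] = anchor + [0.0, y_off - 0.4, 0.0]
                cph = rc.CpHParams(pH=pH, ld_steps_per_cycle=0,
                                   translation_moves=False, seed=3)
                traj = rc.run_cph_ld(st, ff, rc.IntegratorParams(), cph,
                                     n_cycles=500, warmup_cycles=100, rng=rng)
                results[(mode, placement)] = rc.degree_of_ionization(traj.ionization)[0]
        for mode in ("debye_hueckel_implicit_ions", "coulomb_explicit_ions"):
            assert results[(mode, "near")] > results[(mode, "far")] + 0.05
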