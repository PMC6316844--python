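"""Generators: determinism, mass-balance closure, truth consistency, round trips."""

import numpy as np
import pytest

from claysorb.io import read_trajectory, write_trajectory
from claysorb.isotherm import NucleotideSpec, build_isotherm
from claysorb.langmuir import fit_langmuir
from claysorb.md import complex_charge, state_series
from claysorb.normalization import as_normalized, collapse_score, reduce_concentration
from claysorb.synthetic import (
    _SHARED_MINERAL,
    gas_isotherm_scenario,
    gen_gas_isotherm,
    gen_grain_pair,
    gen_homologous_family,
    gen_isotherm,
    gen_trajectory,
    grain_pair_scenario,
    homologous_family_scenario,
    isotherm_scenario,
    trajectory_scenario,
)


class TestDeterminism:
    def test_isotherm_samples_bit_identical(self):
        a = gen_isotherm(isotherm_scenario(5))
        b = gen_isotherm(isotherm_scenario(5))
        assert a == b

    def test_gas_isotherm_bit_identical(self):
        assert gen_gas_isotherm(gas_isotherm_scenario(5)) == gen_gas_isotherm(
            gas_isotherm_scenario(5)
        )

    def test_trajectory_bit_identical(self):
        fa, ta = gen_trajectory(trajectory_scenario(5, n_frames=20))
        fb, tb = gen_trajectory(trajectory_scenario(5, n_frames=20))
        assert ta["states"] == tb["states"]
        for x, y in zip(fa, fb):
            assert np.array_equal(x.coordinates, y.coordinates)

    def test_different_seeds_differ(self):
        a = gen_isotherm(isotherm_scenario(1))
        b = gen_isotherm(isotherm_scenario(2))
        assert a != b


class TestGenIsotherm:
    def test_mass_balance_closes_exactly_before_noise(self):
        from claysorb.synthetic import _truth_q

        scn = isotherm_scenario(0, noise=0.0)
        ratio = scn.truth["mass_g"] / scn.truth["volume_L"]
        for s in gen_isotherm(scn):
            # Ceq solves the implicit model: re-inserting must close the balance
            ceq = s.equilibrium_concentration
            assert ceq + _truth_q(scn.truth, ceq) * ratio == pytest.approx(
                s.initial_concentration, rel=1e-11
            )

    def test_inert_mineral_leaves_concentration_unchanged(self):
        scn = isotherm_scenario(0, q_max=0.0, noise=0.0)
        for s in gen_isotherm(scn):
            assert s.equilibrium_concentration == pytest.approx(
                s.initial_concentration, rel=1e-12
            )

    def test_zero_noise_round_trip_recovers_truth(self, nucleotide):
        scn = isotherm_scenario(0, noise=0.0)
        iso = build_isotherm(gen_isotherm(scn), nucleotide, _SHARED_MINERAL)
        res = fit_langmuir(iso)
        assert abs(res.q_max / scn.truth["q_max"] - 1) < 1e-3
        assert abs(res.k / scn.truth["k"] - 1) < 1e-3


class TestHomologousFamily:
    def test_zero_noise_reduced_collapse_is_exact(self):
        fam = gen_homologous_family(homologous_family_scenario(0, noise=0.0))
        reduced = [reduce_concentration(i) for i in fam]
        assert collapse_score(reduced) == pytest.approx(0.0, abs=1e-12)

    def test_raw_axis_does_not_collapse(self):
        fam = gen_homologous_family(homologous_family_scenario(0, noise=0.0))
        raw = [as_normalized(i) for i in fam]
        assert collapse_score(raw) > 0.1

    def test_single_nucleotide_rejected_at_scenario_level(self):
        with pytest.raises(ValueError, match=">= 2"):
            homologous_family_scenario(0, solubilities=(0.01,))


class TestGrainPair:
    def test_per_gram_plateau_scales_with_edge_area(self):
        isos, minerals = gen_grain_pair(grain_pair_scenario(0, noise=0.0))
        ratio = isos[1].q_ads[-1] / isos[0].q_ads[-1]
        ssa_ratio = minerals[1].ssa_edge / minerals[0].ssa_edge
        assert ratio == pytest.approx(ssa_ratio, rel=1e-12)

    def test_edge_basis_densities_coincide_exactly_without_noise(self):
        from claysorb.normalization import to_density

        isos, _ = gen_grain_pair(grain_pair_scenario(0, noise=0.0))
        da, db = (to_density(i, "edge") for i in isos)
        assert np.allclose(da.d, db.d, rtol=1e-12)


class TestGasIsotherm:
    def test_single_logistic_domain_derivative_peaks_at_u_half(self):
        from claysorb.dis import derivative_isotherm

        scn = gas_isotherm_scenario(0, domains=((1.0, -8.0, 0.0),), noise=0.0)
        deriv = derivative_isotherm(gen_gas_isotherm(scn))
        u = deriv.u_arr
        assert u[np.argmax(deriv.y_arr)] == pytest.approx(-8.0, abs=2 * (u[1] - u[0]))

    def test_blocked_variant_removes_low_u_signal(self):
        blocked = gen_gas_isotherm(gas_isotherm_scenario(0, edge_blocked=True, noise=0.0))
        v = np.asarray(blocked.v_ads)
        u = np.log(np.asarray(blocked.p_over_p0))
        # high-energy (edge) uptake is gone: only the faint basal foot remains,
        # far below the ~0.26 cm^3/g the unblocked edge domain holds there
        assert v[u < -10].max() < 0.01

    def test_invalid_omega_rejected(self):
        with pytest.raises(ValueError):
            gas_isotherm_scenario(0, domains=((1.0, -8.0, 4.2),))


class TestTrajectory:
    def test_stationary_two_sevenths_gives_ratio_point_four(self):
        scn = trajectory_scenario(0)  # Na defaults: p_on 0.02, p_off 0.05
        assert scn.truth["stationary_adsorbed_fraction"] == pytest.approx(2 / 7)
        assert scn.truth["expected_duration_ratio"] == pytest.approx(0.4)

    def test_zero_jitter_classifier_reproduces_truth_exactly(self):
        frames, truth = gen_trajectory(trajectory_scenario(3, n_frames=300, jitter=0.0))
        series = state_series(frames)
        assert series.states.tolist() == truth["states"]

    def test_bound_ion_counts_match_complex_charge(self):
        frames, truth = gen_trajectory(trajectory_scenario(4, n_frames=50, jitter=0.0))
        for frame, k in zip(frames, truth["bound_ions"]):
            assert complex_charge(frame) == pytest.approx(
                -2.0 + truth["ion_charge"] * k
            )

    def test_expected_charges_echo_salt_contrast(self):
        na = trajectory_scenario(0, salt="na").truth
        ca = trajectory_scenario(0, salt="ca").truth
        assert 2.0 < ca["expected_adsorbed_charge"] / na["expected_adsorbed_charge"] < 3.0

    def test_inconsistent_cutoffs_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            trajectory_scenario(0, adsorbed_distance=(2.5, 4.5), cutoff=4.0)

    def test_xyz_round_trip_lossless(self, tmp_path):
        frames, _ = gen_trajectory(trajectory_scenario(6, n_frames=4))
        xyz, roles = tmp_path / "t.xyz", tmp_path / "roles.csv"
        write_trajectory(xyz, roles, frames)
        back = read_trajectory(xyz, roles)
        assert len(back) == len(frames)
        for a, b in zip(frames, back):
            assert np.array_equal(a.coordinates, b.coordinates)
            assert a.roles == b.roles
            assert np.array_equal(a.charges, b.charges)
            assert a.ring_atoms == b.ring_atoms
            assert a.time == b.time and a.box == b.box
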