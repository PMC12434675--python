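import math

import numpy as np
import pytest

from crossbeta.field_dynamics import (
    E_FIELD_FORCE_FACTOR,
    KB_KJ_PER_MOL_K,
    ENMSystem,
    FieldSpec,
    build_enm,
    field_at,
    field_force,
    fit_response_amplitude,
    response_amplitude,
    simulate,
)


def one_bead(charge=0.0, k=100.0, gamma=50.0, temperature=300.0):
    return ENMSystem(
        positions_nm=np.zeros((1, 3)),
        charges_e=np.array([charge]),
        springs=np.zeros((0, 2)),
        stiffness=np.zeros(0),
        rest_lengths_nm=np.zeros(0),
        gamma=gamma,
        temperature_k=temperature,
        tether_k=np.array([k]) if k else None,
    )


class TestFieldSpec:
    def test_axis_normalised(self):
        spec = FieldSpec(e0_mv_per_nm=100, frequency_ghz=1, axis=(3, 0, 4))
        np.testing.assert_allclose(spec.axis, (0.6, 0.0, 0.8))

    def test_period_10ghz(self):
        assert FieldSpec(frequency_ghz=10.0).period_ns == pytest.approx(0.1)

    def test_static_field(self):
        spec = FieldSpec(e0_mv_per_nm=50, frequency_ghz=0.0)
        assert spec.period_ns == math.inf
        np.testing.assert_allclose(field_at(123.0, spec), [50, 0, 0])

    def test_invalid(self):
        with pytest.raises(ValueError):
            FieldSpec(e0_mv_per_nm=-1)
        with pytest.raises(ValueError):
            FieldSpec(frequency_ghz=-1)
        with pytest.raises(ValueError):
            FieldSpec(axis=(0, 0, 0))


class TestFieldAt:
    def test_t0_full_strength(self):
        spec = FieldSpec(e0_mv_per_nm=200, frequency_ghz=1, axis=(0, 0, 1))
        np.testing.assert_allclose(field_at(0.0, spec), [0, 0, 200])

    def test_quarter_period_zero(self):
        spec = FieldSpec(e0_mv_per_nm=200, frequency_ghz=1)
        quarter = 0.25 * spec.period_ns * 1000  # ps
        np.testing.assert_allclose(
            field_at(quarter, spec), [0, 0, 0], atol=1e-10
        )

    def test_period_repeats(self):
        spec = FieldSpec(e0_mv_per_nm=100, frequency_ghz=10)
        period_ps = spec.period_ns * 1000
        for t in (3.0, 17.0, 42.0):
            np.testing.assert_allclose(
                field_at(t, spec), field_at(t + period_ps, spec), atol=1e-9
            )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            field_at(-1.0, FieldSpec())


class TestFieldForce:
    def test_unit_conversion(self):
        f = field_force(1.0, np.array([100.0, 0, 0]))
        np.testing.assert_allclose(f, [9.6485, 0, 0])

    def test_zero_charge(self):
        np.testing.assert_allclose(
            field_force(0.0, np.array([500.0, 0, 0])), 0.0
        )

    def test_sign_flip(self):
        e = np.array([100.0, 0, 0])
        np.testing.assert_allclose(field_force(-1.0, e), -field_force(1.0, e))


class TestSimulate:
    def test_free_diffusion_msd(self):
        gamma = 50.0
        d_coef = KB_KJ_PER_MOL_K * 300 / gamma
        dt, stride = 0.05, 50
        msds = []
        for rep in range(40):
            traj = simulate(
                one_bead(k=0.0, gamma=gamma), FieldSpec(),
                dt_ps=dt, n_steps=2000, stride=stride, seed=rep,
            )
            steps = np.diff(traj.frames_nm[:, 0, :], axis=0)
            msds.append((steps**2).sum(axis=1).mean())
        expected = 6 * d_coef * dt * stride
        assert np.mean(msds) == pytest.approx(expected, rel=0.05)

    def test_equipartition(self):
        k = 100.0
        traj = simulate(
            one_bead(k=k), FieldSpec(),
            dt_ps=0.02, n_steps=120000, stride=10, seed=1,
        )
        var = traj.frames_nm[600:, 0, :].var(axis=0)
        expected = KB_KJ_PER_MOL_K * 300 / k
        np.testing.assert_allclose(var, expected, rtol=0.05)

    @pytest.mark.parametrize("nu", [0.1, 1.0, 10.0])
    def test_driven_amplitude_matches_closed_form(self, nu):
        k, gamma = 100.0, 50.0
        spec = FieldSpec(e0_mv_per_nm=200, frequency_ghz=nu, axis=(1, 0, 0))
        predicted = response_amplitude(1.0, k, gamma, spec)
        period_ps = 1000.0 / nu
        n_steps = int(min(20 * period_ps, 200000) / 0.04)
        traj = simulate(
            one_bead(charge=1.0, k=k, gamma=gamma, temperature=0.0), spec,
            dt_ps=0.04, n_steps=n_steps, stride=5, seed=0,
        )
        measured = fit_response_amplitude(
            traj.times_ns * 1000, traj.frames_nm[:, 0, 0], spec
        )
        assert measured == pytest.approx(predicted, rel=0.05)

    def test_linearity_in_field_strength(self):
        k = 100.0
        amps = []
        for e0 in (100.0, 200.0):
            spec = FieldSpec(e0_mv_per_nm=e0, frequency_ghz=1.0)
            traj = simulate(
                one_bead(charge=1.0, k=k, temperature=0.0), spec,
                dt_ps=0.04, n_steps=50000, stride=5, seed=0,
            )
            amps.append(fit_response_amplitude(
                traj.times_ns * 1000, traj.frames_nm[:, 0, 0], spec
            ))
        assert amps[1] == pytest.approx(2 * amps[0], rel=1e-6)

    def test_bit_reproducible(self):
        t1 = simulate(one_bead(k=50.0), FieldSpec(), dt_ps=0.05,
                      n_steps=500, stride=10, seed=4)
        t2 = simulate(one_bead(k=50.0), FieldSpec(), dt_ps=0.05,
                      n_steps=500, stride=10, seed=4)
        np.testing.assert_array_equal(t1.frames_nm, t2.frames_nm)

    def test_unstable_timestep_rejected(self):
        with pytest.raises(ValueError, match="unstable timestep"):
            simulate(one_bead(k=1000.0, gamma=10.0), FieldSpec(),
                     dt_ps=1.0, n_steps=10, stride=1, seed=0)

    def test_zero_charge_field_independent(self):
        args = dict(dt_ps=0.05, n_steps=300, stride=10, seed=6)
        quiet = simulate(one_bead(charge=0.0, k=50.0), FieldSpec(), **args)
        loud = simulate(
            one_bead(charge=0.0, k=50.0),
            FieldSpec(e0_mv_per_nm=500, frequency_ghz=1.0), **args,
        )
        np.testing.assert_array_equal(quiet.frames_nm, loud.frames_nm)


class TestTrajectoryEnergies:
    def test_rest_frame_zero_spring_energy(self, phf_structure, phf_assembly):
        from crossbeta.field_dynamics import trajectory_energies

        system = build_enm(phf_structure, phf_assembly, k=50.0, gamma=2500.0)
        spec = FieldSpec(e0_mv_per_nm=100, frequency_ghz=1.0)
        traj = simulate(system, spec, dt_ps=0.5, n_steps=200, stride=100,
                        seed=0)
        energies = trajectory_energies(system, traj, spec)
        assert energies["spring_kj_mol"][0] == pytest.approx(0.0, abs=1e-9)
        assert len(energies["field_kj_mol"]) == traj.n_frames
        # thermal motion stretches springs: energy grows from rest
        assert energies["spring_kj_mol"][1:].min() > 0.0


class TestResponseAmplitude:
    def test_static_limit(self):
        spec = FieldSpec(e0_mv_per_nm=100, frequency_ghz=0.0)
        k = 50.0
        expected = field_force(1.0, np.array([100.0]))[0] / k
        assert response_amplitude(1.0, k, 50.0, spec) == pytest.approx(expected)

    def test_monotone_decreasing_in_frequency(self):
        amps = [
            response_amplitude(
                1.0, 50.0, 500.0,
                FieldSpec(e0_mv_per_nm=100, frequency_ghz=nu),
            )
            for nu in (0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a > b for a, b in zip(amps, amps[1:]))

    def test_linear_in_e0(self):
        a1 = response_amplitude(
            1.0, 50.0, 50.0, FieldSpec(e0_mv_per_nm=100, frequency_ghz=1)
        )
        a2 = response_amplitude(
            1.0, 50.0, 50.0, FieldSpec(e0_mv_per_nm=200, frequency_ghz=1)
        )
        assert a2 == pytest.approx(2 * a1)


class TestBuildENM:
    def test_bead_per_residue_with_charges(self, phf_structure, phf_assembly):
        system = build_enm(phf_structure, phf_assembly)
        assert system.n_beads == 770
        # per chain: K/R count vs D/E count of the tau core
        from crossbeta.fibril_model import tau_core_spec

        charges = tau_core_spec().charges()
        per_chain = system.charges_e[:77]
        np.testing.assert_array_equal(per_chain, charges)

    def test_interprotofilament_springs_weaker(
        self, phf_structure, phf_assembly
    ):
        system = build_enm(
            phf_structure, phf_assembly, k=500.0, k_interprotofilament=50.0
        )
        pf = np.array([
            phf_assembly.protofilament_of[c] for c in system.chain_of_bead
        ])
        cross = pf[system.springs[:, 0]] != pf[system.springs[:, 1]]
        assert cross.any()
        assert set(system.stiffness[cross]) == {50.0}
        assert set(system.stiffness[~cross]) == {500.0}

    def test_spring_graph_connected_within_chain(
        self, phf_structure, phf_assembly
    ):
        system = build_enm(phf_structure, phf_assembly)
        # consecutive beads of one chain are always within the cutoff
        chain_a = system.chain_of_bead == "A"
        idx = np.flatnonzero(chain_a)
        pairs = {tuple(sorted(p)) for p in system.springs.tolist()}
        for i, j in zip(idx[:-1], idx[1:]):
            assert (i, j) in pairs
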