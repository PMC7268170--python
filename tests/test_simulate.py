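"""Integrator against analytic and fixed-point oracles; trajectory contracts."""

import math

import numpy as np
import pytest

from nitroforage import (
    ExperimentSpec,
    LayerFlags,
    ModelParameters,
    analytic_length,
    integrate,
    pool_steady_state,
)

P = ModelParameters()


@pytest.mark.parametrize(
    "t, L0, r, conv, expected",
    [
        (0.0, 20.0, 1.0, 0.01, 20.0),
        (240.0, 20.0, 1.5, math.log(36.0) / 360.0, 720.0),
        (192.0, 20.0, 1.0, 0.01, 20.0 * math.exp(1.92)),
    ],
)
def test_analytic_length_values(t, L0, r, conv, expected):
    assert analytic_length(t, L0, r, conv) == pytest.approx(expected, rel=1e-12)


def test_analytic_length_rejects_negative_arguments():
    with pytest.raises(ValueError):
        analytic_length(-1.0, 20.0, 1.0, 0.01)


def test_unregulated_growth_matches_exponential_solution():
    """All layers off ⇒ the integrator must track L0·exp(conv·t) to 1e-6
    relative at every hourly sample over 240 h."""
    spec = ExperimentSpec(ne=(1000.0,), duration=240.0, L0=(20.0,),
                          flags=LayerFlags.none())
    traj = integrate(spec, P)
    expected = analytic_length(traj.times, 20.0, 1.0, P.conv)
    np.testing.assert_allclose(traj.L[:, 0], expected, rtol=1e-6)
    assert traj.L[-1, 0] == pytest.approx(20.0 * math.exp(2.4), rel=1e-6)


def test_zero_duration_returns_initial_condition():
    spec = ExperimentSpec(ne=(25.0, 5000.0), duration=0.0)
    traj = integrate(spec, P)
    assert traj.times.shape == (1,)
    np.testing.assert_array_equal(traj.L[0], [20.0, 20.0])
    np.testing.assert_array_equal(traj.Ni[0], 0.0)


def test_symmetric_split_root_trajectories_identical():
    spec = ExperimentSpec(ne=(5000.0, 5000.0), duration=144.0)
    traj = integrate(spec, P)
    np.testing.assert_allclose(traj.L[:, 0], traj.L[:, 1], rtol=1e-12)
    np.testing.assert_allclose(traj.Ni[:, 0], traj.Ni[:, 1], rtol=1e-12)


def test_trajectory_contracts():
    spec = ExperimentSpec(ne=(25.0, 5000.0), duration=144.0)
    traj = integrate(spec, P)
    assert np.all(np.diff(traj.times) > 0)
    assert traj.times[0] == 0.0 and traj.times[-1] == 144.0
    np.testing.assert_array_equal(traj.L[0], spec.L0_array)
    assert np.all(np.diff(traj.L, axis=0) >= -1e-9)  # growth never negative
    assert np.isfinite(traj.to_frame().to_numpy(dtype=float)).all()
    assert traj.L.min() > 0 and traj.Ni.min() >= 0


@pytest.mark.parametrize(
    "ne, expected_ni",
    [
        (0.0, 0.0),
        # closed form (up1·Ne/(Ne+K_up) + up2·Ne)/T_up at L = 1 mm
        (1000.0, (0.6 * 1000.0 / 1075.0 + 6e-6 * 1000.0) / 3.8),
    ],
)
def test_pool_steady_state_closed_forms(ne, expected_ni):
    Ni, Ns, CEP, CEPs, CK, CKs = pool_steady_state(
        np.array([1.0]), np.array([ne]), P, LayerFlags.full()
    )
    assert Ni[0] == pytest.approx(expected_ni, rel=1e-12)
    if ne == 0.0:
        assert CK[0] == 0.0 and CKs == 0.0
        assert CEP[0] == pytest.approx(P.p_CEP * 1.0 / P.T_CEP)
        assert Ns == 0.0  # maintenance exceeds uptake: pool clipped at empty


def test_pool_steady_state_scales_linearly_with_length():
    one = pool_steady_state(np.array([1.0]), np.array([500.0]), P,
                            LayerFlags.full())
    seven = pool_steady_state(np.array([7.0]), np.array([500.0]), P,
                              LayerFlags.full())
    assert seven[0][0] == pytest.approx(7 * one[0][0], rel=1e-12)
    assert seven[2][0] == pytest.approx(7 * one[2][0], rel=1e-12)


def test_frozen_length_integration_converges_to_fixed_points():
    """With conv = 0 lengths are frozen; nitrate pools must reach the closed
    forms to 1e-6 relative, the slow CEP/CK systemic pools approach theirs
    monotonically from below."""
    p0 = P.replace(conv=0.0)
    spec = ExperimentSpec(ne=(25.0, 5000.0), duration=100.0,
                          L0=(20.0, 20.0), flags=LayerFlags.full())
    traj = integrate(spec, p0)
    Ni, Ns, CEP, CEPs, CK, CKs = pool_steady_state(
        spec.L0_array, spec.ne_array, p0, spec.flags
    )
    np.testing.assert_array_equal(traj.L[-1], spec.L0_array)
    np.testing.assert_allclose(traj.Ni[-1], Ni, rtol=1e-6)
    assert traj.Ns[-1] == pytest.approx(Ns, rel=1e-6)
    np.testing.assert_allclose(traj.CEP[-1], CEP, rtol=1e-4)
    for series, limit in ((traj.CEPs, CEPs), (traj.CKs, CKs)):
        assert np.all(np.diff(series) >= -1e-9)
        assert np.all(series <= limit * (1 + 1e-9))


def test_reported_lengths_robust_to_tighter_tolerances():
    spec = ExperimentSpec(ne=(25.0, 5000.0), duration=144.0)
    base = integrate(spec, P).final_lengths
    tight = integrate(spec, P, rtol=1e-9, atol=1e-11).final_lengths
    assert np.max(np.abs(base - tight)) < 0.1


def test_integrate_applies_mutant_overrides():
    spec_wt = ExperimentSpec(ne=(25.0, 5000.0), duration=144.0)
    spec_mut = ExperimentSpec(ne=(25.0, 5000.0), duration=144.0, mutant="nrt1.1")
    wt = integrate(spec_wt, P).final_lengths
    mut = integrate(spec_mut, P).final_lengths
    assert mut[1] < wt[1]  # blunted local response shrinks the high side
    assert mut[0] > wt[0]


def test_steady_state_initialization_pre_equilibrates_pools():
    spec = ExperimentSpec(ne=(25.0, 5000.0), duration=0.0,
                          init_pools="steady_state")
    traj = integrate(spec, P)
    Ni, Ns, *_ = pool_steady_state(spec.L0_array, spec.ne_array, P, spec.flags)
    np.testing.assert_allclose(traj.Ni[0], Ni, rtol=1e-12)
    assert traj.Ns[0] == pytest.approx(Ns, rel=1e-12)
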