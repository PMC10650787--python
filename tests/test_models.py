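"""Forward compartment models: impulse response, convolution, frame averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from petkin import (
    ExtrapolationError,
    KineticParams1TC,
    KineticParams2TC,
    TimeActivityCurve,
    impulse_response_2tc,
    interpolate_input,
    make_frame_schedule,
    simulate_tissue_tac,
)
from petkin.tac import FrameSchedule

from conftest import params_from_table


def ode_frame_averages(params, blood, schedule, rtol=1e-10):
    """Independent oracle: stiff integration of the compartment ODEs driven by
    the same piecewise-linear input, with an auxiliary state for the exact
    per-frame time-average of the measured signal."""
    inp = interpolate_input(blood, t_end=schedule.total_duration)

    def cb(t):
        return np.interp(t, inp.times, inp.values)

    if isinstance(params, KineticParams1TC):
        K1, k2, k3, k4 = params.K1, params.k2, 0.0, 0.0
    else:
        K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    vp = params.vp

    def rhs(t, y):
        c1, c2, _ = y
        return [
            K1 * cb(t) - (k2 + k3) * c1 + k4 * c2,
            k3 * c1 - k4 * c2,
            (1 - vp) * (c1 + c2) + vp * cb(t),
        ]

    tpts = np.unique(np.concatenate([schedule.starts, schedule.ends]))
    sol = solve_ivp(rhs, (0.0, schedule.total_duration), [0.0, 0.0, 0.0],
                    t_eval=tpts, method="LSODA", rtol=rtol, atol=1e-14,
                    max_step=min(0.25, float(np.min(schedule.durations))))
    cum = dict(zip(sol.t, sol.y[2]))
    return np.array([
        (cum[e] - cum[s]) / (e - s) for s, e in zip(schedule.starts, schedule.ends)
    ])


class TestImpulseResponse:
    def test_published_wild_type_thalamus_identities(self):
        # alpha1+alpha2 = k2+k3+k4 and alpha1*alpha2 = k2*k4, analytic identities
        p = KineticParams2TC(K1=0.098, k2=0.075, k3=0.029, k4=0.0077)
        ir = impulse_response_2tc(p)
        assert ir.alpha1 + ir.alpha2 == pytest.approx(0.1117, abs=1e-12)
        assert ir.alpha1 * ir.alpha2 == pytest.approx(5.775e-4, rel=1e-10)
        assert ir.A1 + ir.A2 == pytest.approx(p.K1, rel=1e-10)

    def test_no_binding_collapses_to_one_tissue(self):
        p = KineticParams2TC(K1=0.3, k2=0.2, k3=0.0, k4=0.05)
        ir = impulse_response_2tc(p)
        assert sorted([ir.alpha1, ir.alpha2]) == pytest.approx([0.05, 0.2])

    @given(
        K1=st.floats(0.0001, 5), k2=st.floats(0.0001, 5),
        k3=st.floats(0.0001, 5), k4=st.floats(0.0001, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_eigen_invariants_across_parameter_box(self, K1, k2, k3, k4):
        p = KineticParams2TC(K1=K1, k2=k2, k3=k3, k4=k4)
        ir = impulse_response_2tc(p)
        s, prod = k2 + k3 + k4, k2 * k4
        assert 0 <= ir.alpha1 <= ir.alpha2
        assert ir.alpha1 + ir.alpha2 == pytest.approx(s, rel=1e-10)
        assert ir.alpha1 * ir.alpha2 == pytest.approx(prod, rel=1e-6, abs=1e-12)
        if not ir.repeated:
            # eigenvalues of the state matrix [[-(k2+k3), k4], [k3, -k4]]
            eig = np.linalg.eigvals(np.array([[-(k2 + k3), k4], [k3, -k4]]))
            assert sorted(-eig) == pytest.approx(
                [ir.alpha1, ir.alpha2], rel=1e-8, abs=1e-12
            )
            assert ir.A1 + ir.A2 == pytest.approx(K1, rel=1e-8, abs=1e-12)

    def test_bp_nd_requires_positive_k4(self):
        with pytest.raises(ValueError):
            KineticParams2TC(K1=0.1, k2=0.1, k3=0.1, k4=0.0).bp_nd


class TestInterpolateInput:
    def test_nodes_and_origin(self, blood_2fa):
        inp = interpolate_input(blood_2fa)
        mids = blood_2fa.schedule.midpoints
        assert inp(0.0) == 0.0
        # midpoints of the 600-s frames lie on the 0.25-min grid
        assert np.allclose(inp(mids), blood_2fa.values)

    def test_cumulative_matches_trapezoid(self, blood_2fa):
        inp = interpolate_input(blood_2fa)
        ref = np.trapezoid(inp.values, inp.times)
        assert inp.cumulative[-1] == pytest.approx(ref, rel=1e-12)


class TestSimulateTissueTac:
    def test_no_extraction_returns_blood_volume_term(self, blood_2fa, sched_2fa):
        p = KineticParams2TC(K1=0.0, k2=0.1, k3=0.0, k4=0.0, vp=0.08)
        out = simulate_tissue_tac(p, blood_2fa, sched_2fa)
        blood_avg = simulate_tissue_tac(
            KineticParams2TC(K1=0.0, k2=0.1, k3=0.0, k4=0.0, vp=1.0),
            blood_2fa, sched_2fa,
        )
        assert np.allclose(out.values, 0.08 * blood_avg.values, rtol=1e-12)

    def test_zero_input_and_linearity(self, blood_2fa, sched_2fa):
        p = params_from_table("2-FA", "WT", "thalamus")
        zero = blood_2fa.with_values(np.zeros_like(blood_2fa.values))
        assert np.all(simulate_tissue_tac(p, zero, sched_2fa).values == 0)
        one = simulate_tissue_tac(p, blood_2fa, sched_2fa).values
        twice = simulate_tissue_tac(
            p, blood_2fa.with_values(2 * blood_2fa.values), sched_2fa
        ).values
        assert np.allclose(twice, 2 * one, rtol=1e-13)

    def test_nesting_two_tissue_matches_one_tissue(self, blood_2fa, sched_2fa):
        p2 = KineticParams2TC(K1=0.4, k2=0.15, k3=0.0, k4=0.0, vp=0.05)
        p1 = KineticParams1TC(K1=0.4, k2=0.15, vp=0.05)
        v2 = simulate_tissue_tac(p2, blood_2fa, sched_2fa).values
        v1 = simulate_tissue_tac(p1, blood_2fa, sched_2fa).values
        assert np.allclose(v2, v1, rtol=1e-8)

    def test_matches_ode_oracle_on_published_means(self, blood_2fa, sched_2fa):
        p = params_from_table("2-FA", "WT", "thalamus")
        ours = simulate_tissue_tac(p, blood_2fa, sched_2fa).values
        oracle = ode_frame_averages(p, blood_2fa, sched_2fa)
        assert np.max(np.abs(ours - oracle) / np.abs(oracle)) < 1e-3

    def test_repeated_eigenvalue_limit_against_split_roots(self, blood_2fa, sched_2fa):
        # k3=0 with k2=k4 makes the two eigenvalues coincide exactly
        p = KineticParams2TC(K1=0.2, k2=0.1, k3=0.0, k4=0.1, vp=0.02)
        assert impulse_response_2tc(p).repeated
        ours = simulate_tissue_tac(p, blood_2fa, sched_2fa).values
        eps = 1e-5
        near = KineticParams2TC(K1=0.2, k2=0.1 + eps, k3=0.0, k4=0.1 - eps, vp=0.02)
        split = simulate_tissue_tac(near, blood_2fa, sched_2fa).values
        assert np.allclose(ours, split, rtol=1e-3)
        oracle = ode_frame_averages(p, blood_2fa, sched_2fa)
        assert np.max(np.abs(ours - oracle) / np.abs(oracle)) < 1e-3

    def test_steady_state_reaches_total_volume_of_distribution(self):
        p = KineticParams2TC(K1=0.3, k2=0.15, k3=0.05, k4=0.02, vp=0.04)
        sched = FrameSchedule(
            starts=np.arange(0.0, 3000.0, 10.0), ends=np.arange(10.0, 3010.0, 10.0)
        )
        const = TimeActivityCurve(schedule=sched, values=np.full(300, 2.0), unit="SUV")
        out = simulate_tissue_tac(p, const, sched)
        vt = (1 - p.vp) * (p.K1 / p.k2) * (1 + p.k3 / p.k4) * 2.0 + p.vp * 2.0
        assert out.values[-1] == pytest.approx(vt, rel=5e-3)

    def test_schedule_beyond_blood_support_raises(self, blood_nifene):
        long_sched = make_frame_schedule([(10, 600)])  # 100 min > 60 min scan
        p = KineticParams1TC(K1=0.1, k2=0.1)
        with pytest.raises(ExtrapolationError):
            simulate_tissue_tac(p, blood_nifene, long_sched)
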