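"""Thermoelastic wave-solver tests: closed-form limits, modal accuracy,
stress focusing and symmetry."""

import numpy as np
import pytest

from freywave.phantom import build_layered_head
from freywave.thermal import TemperatureLoad
from freywave.elastodynamics import (
    AcousticMedium, ProbeTrace, characteristic_time,
    inertial_confinement_pressure, solve_spherical, solve_cartesian,
    nearest_resample,
)
from freywave.injury_metrics import pressure_spectrum, tensile_arrival_time

RHO, C = 1040.0, 1450.0
K = RHO * C * C
BETA = 3.6e-4
A = 0.075
TC = A / C


@pytest.fixture(scope="module")
def brain_medium():
    return AcousticMedium(rho=RHO, K=K, beta=BETA)


def surface_weighted_dT(n_shells, peak=1e-3, decay=0.02):
    r = (np.arange(n_shells) + 0.5) * A / n_shells
    return peak * np.exp(-(A - r) / decay)


class TestClosedForms:
    def test_characteristic_time_head(self):
        """a = 0.085 m, c = 1450 m/s: transit time about 59 us."""
        tc = characteristic_time(0.085, 1450.0)
        assert tc == pytest.approx(5.862e-5, rel=1e-3)

    def test_characteristic_time_degenerate_and_linear(self):
        assert characteristic_time(0.0, 1000.0) == 0.0
        assert characteristic_time(0.2, 1450.0) == pytest.approx(
            2 * characteristic_time(0.1, 1450.0))

    def test_inertial_confinement_arithmetic(self):
        assert inertial_confinement_pressure(2.19e9, 3.6e-4, 1e-3) == \
            pytest.approx(788.4)
        assert inertial_confinement_pressure(2.19e9, 3.6e-4, 0.0) == 0.0
        assert inertial_confinement_pressure(2.19e9, 3.6e-4, 2e-3) == \
            pytest.approx(2 * 788.4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            characteristic_time(-0.1, 1450.0)
        with pytest.raises(ValueError):
            inertial_confinement_pressure(-1.0, 3.6e-4, 1e-3)


class TestSphericalSolver:
    def test_no_forcing_no_pressure(self, brain_medium):
        load = TemperatureLoad(delta_T=np.zeros(64), tau_d=1e-6, pin=1.0)
        res = solve_spherical(brain_medium, load, duration=5 * TC,
                              n_shells=64, radius=A,
                              probe_radii={"c": 0.02})
        assert np.all(res.pressure_history == 0.0)
        assert np.all(res.traces[0].pressure == 0.0)

    def test_inertial_confinement_plateau(self, brain_medium):
        """Instant uniform heating, rigid wall: p = K beta dT exactly."""
        load = TemperatureLoad(delta_T=np.full(128, 1e-3), tau_d=1e-9,
                               pin=1.0)
        res = solve_spherical(brain_medium, load, duration=5e-6,
                              boundary="rigid", n_shells=128, radius=A)
        want = K * BETA * 1e-3
        assert res.pressure_history[-1] == pytest.approx(want, rel=0.02)

    def test_fundamental_mode_frequency(self, brain_medium):
        """Free sphere fundamental c/(2a), within 2% at 128 shells."""
        load = TemperatureLoad(delta_T=surface_weighted_dT(128),
                               tau_d=5e-6, pin=1.0)
        res = solve_spherical(brain_medium, load, duration=6e-3,
                              boundary="pressure_release", n_shells=128,
                              radius=A, probe_radii={"m": 0.5 * A})
        peak = pressure_spectrum(res.traces[0]).dominant_peak
        assert peak == pytest.approx(C / (2 * A), rel=0.02)

    def test_modal_error_decreases_with_refinement(self, brain_medium):
        errs = []
        for n in (32, 128):
            load = TemperatureLoad(delta_T=surface_weighted_dT(n),
                                   tau_d=5e-6, pin=1.0)
            res = solve_spherical(brain_medium, load, duration=6e-3,
                                  boundary="pressure_release", n_shells=n,
                                  radius=A, probe_radii={"m": 0.5 * A})
            peak = pressure_spectrum(res.traces[0]).dominant_peak
            errs.append(abs(peak - C / (2 * A)))
        assert errs[1] < errs[0]

    def test_equilibrium_limit_residual(self, brain_medium):
        """tau_d >> tau_c, uniform dT, free surface: residual stress
        below 5% of the confinement pressure."""
        load = TemperatureLoad(delta_T=np.full(256, 1e-3), tau_d=50 * TC,
                               pin=1.0)
        res = solve_spherical(brain_medium, load, duration=56 * TC,
                              boundary="pressure_release", n_shells=256,
                              radius=A)
        after = res.snapshot_times > 51 * TC
        resid = np.abs(res.pressure_history[after]).max()
        assert resid < 0.05 * K * BETA * 1e-3

    def test_focusing_monotone_in_pulse_duration(self, brain_medium):
        """Equal final dT: peak tensile pressure non-increasing in
        tau_d/tau_c over {0.1, 1, 10}."""
        peaks = []
        for ratio in (0.1, 1.0, 10.0):
            load = TemperatureLoad(delta_T=surface_weighted_dT(256),
                                   tau_d=ratio * TC, pin=1.0)
            res = solve_spherical(brain_medium, load,
                                  duration=(ratio + 8) * TC,
                                  boundary="pressure_release", n_shells=256,
                                  radius=A)
            peaks.append(-res.pressure_history.min())
        assert peaks[0] >= peaks[1] >= peaks[2]
        assert peaks[2] < 0.1 * peaks[0]

    def test_linearity_in_temperature(self, brain_medium):
        load1 = TemperatureLoad(delta_T=surface_weighted_dT(64),
                                tau_d=5e-6, pin=1.0)
        load2 = TemperatureLoad(delta_T=3 * surface_weighted_dT(64),
                                tau_d=5e-6, pin=1.0)
        r1 = solve_spherical(brain_medium, load1, duration=3 * TC,
                             n_shells=64, radius=A)
        r2 = solve_spherical(brain_medium, load2, duration=3 * TC,
                             n_shells=64, radius=A)
        assert np.allclose(r2.pressure_history, 3 * r1.pressure_history,
                           rtol=1e-9, atol=1e-12)

    def test_energy_bounded_after_forcing(self, brain_medium):
        """Free sphere rings without numerical blow-up over 10 tau_c."""
        load = TemperatureLoad(delta_T=surface_weighted_dT(128),
                               tau_d=0.1 * TC, pin=1.0)
        res = solve_spherical(brain_medium, load, duration=12 * TC,
                              boundary="pressure_release", n_shells=128,
                              radius=A)
        early = np.abs(res.pressure_history[
            res.snapshot_times < 2 * TC]).max()
        late = np.abs(res.pressure_history[
            res.snapshot_times > 10 * TC]).max()
        assert np.isfinite(late)
        assert late < 2.0 * early

    def test_bad_probe_and_boundary_rejected(self, brain_medium):
        load = TemperatureLoad(delta_T=np.zeros(32), tau_d=1e-6, pin=1.0)
        with pytest.raises(ValueError, match="probe"):
            solve_spherical(brain_medium, load, duration=1e-5, n_shells=32,
                            radius=A, probe_radii={"x": 2 * A})
        with pytest.raises(ValueError, match="boundary"):
            solve_spherical(brain_medium, load, duration=1e-5, n_shells=32,
                            radius=A, boundary="absorbing")


@pytest.fixture(scope="module")
def small_head():
    return build_layered_head(outer_diameter=0.10, spacing=2.5e-3,
                              shape="sphere", ventricles=False)


def front_weighted_load(ph, peak=1e-3, decay=0.01):
    # decay must stay well below the brain radius for the load to be
    # genuinely front-weighted (the small test head is 0.10 m across)
    brain = ph.brain_mask()
    ys = np.nonzero(brain.any(axis=(0, 2)))[0]
    yy = np.arange(ph.labels.shape[1])
    w = np.exp(-(yy - ys[0]) * ph.spacing / decay)
    return np.where(brain, peak * w[None, :, None], 0.0)


class TestCartesianSolver:
    def test_symmetric_load_symmetric_pressure(self, small_head):
        """A front-weighted load that is mirror symmetric about the
        midsagittal plane gives a mirror-symmetric pressure field (<=1%)."""
        load = TemperatureLoad(delta_T=front_weighted_load(small_head),
                               tau_d=5e-6, pin=1.0)
        res = solve_cartesian(small_head, load, duration=1.5e-4)
        m = res.min_pressure
        asym = np.abs(m - m[::-1, :, :]).max()
        assert asym < 0.01 * np.abs(m).max()

    def test_occipital_lag_and_deep_focusing(self, small_head):
        """Front-weighted short pulse: the tensile focus arrives at the
        occipital probe about 2 tau_c after the frontal probe, and the
        most tensile voxels lie deep, not at the heated surface."""
        load = TemperatureLoad(delta_T=front_weighted_load(small_head),
                               tau_d=2e-6, pin=1.0)
        brain = small_head.brain_mask()
        ys = np.nonzero(brain.any(axis=(0, 2)))[0]
        a = (ys[-1] - ys[0] + 1) * small_head.spacing / 2
        tc = characteristic_time(a, 1450.0)
        res = solve_cartesian(small_head, load, duration=6 * tc)
        arrivals = {tr.name: tensile_arrival_time(tr) for tr in res.traces}
        lag = arrivals["occipital"] - arrivals["frontal"]
        assert lag == pytest.approx(2 * tc, rel=0.35)
        # deep focusing: most tensile voxel far from the heated surface
        idx = np.unravel_index(np.argmin(res.min_pressure),
                               res.min_pressure.shape)
        depth_vox = idx[1] - ys[0] * small_head.spacing / res.spacing
        assert depth_vox * res.spacing > 0.25 * a

    def test_pressure_scales_with_temperature(self, small_head):
        dT = front_weighted_load(small_head)
        r1 = solve_cartesian(small_head,
                             TemperatureLoad(delta_T=dT, tau_d=5e-6, pin=1.0),
                             duration=1e-4)
        r2 = solve_cartesian(small_head,
                             TemperatureLoad(delta_T=5 * dT, tau_d=5e-6,
                                             pin=1.0),
                             duration=1e-4)
        assert np.allclose(r2.min_pressure, 5 * r1.min_pressure,
                           rtol=1e-9, atol=1e-9)

    def test_wave_grid_resampling(self, small_head):
        load = TemperatureLoad(delta_T=front_weighted_load(small_head),
                               tau_d=5e-6, pin=1.0)
        res = solve_cartesian(small_head, load, duration=5e-5,
                              spacing=5e-3)
        assert res.spacing == 5e-3
        assert res.min_pressure.shape == tuple(
            s // 2 for s in small_head.labels.shape)

    def test_probe_outside_brain_rejected(self, small_head):
        load = TemperatureLoad(
            delta_T=np.zeros(small_head.labels.shape), tau_d=5e-6, pin=1.0)
        with pytest.raises(ValueError, match="probe"):
            solve_cartesian(small_head, load, duration=1e-5,
                            probes={"bad": (0, 0, 0)})

    def test_strain_tracked_and_small(self, small_head):
        load = TemperatureLoad(delta_T=front_weighted_load(small_head),
                               tau_d=5e-6, pin=1.0)
        res = solve_cartesian(small_head, load, duration=1e-4)
        assert res.mps > 0.0
        assert res.max_strain_rate > 0.0
        assert res.mps < 1e-4  # millidegree heating produces tiny strains


class TestDirectionalEffects:
    """Front vs side exposure: the deep-brain response frequency is set by
    the geometry, not the load direction, while the amplitude changes."""

    @pytest.fixture(scope="class")
    def two_direction_runs(self):
        ph = build_layered_head(outer_diameter=0.10, spacing=2.5e-3,
                                shape="ellipsoid", ventricles=False)
        brain = ph.brain_mask()
        out = {}
        for axis in (1, 0):  # frontal (+y analogue) then side (+x)
            ns = np.nonzero(brain.any(axis=tuple({0, 1, 2} - {axis})))[0]
            coord = np.arange(ph.labels.shape[axis])
            w = np.exp(-(coord - ns[0]) * ph.spacing / 0.01)
            shape = [1, 1, 1]
            shape[axis] = -1
            dT = np.where(brain, 1e-3 * w.reshape(shape), 0.0)
            load = TemperatureLoad(delta_T=dT, tau_d=5e-6, pin=1.0)
            out[axis] = solve_cartesian(ph, load, duration=2e-3)
        return out

    def test_deep_probe_frequency_direction_invariant(self,
                                                      two_direction_runs):
        specs = {}
        for axis, res in two_direction_runs.items():
            tr = next(t for t in res.traces if t.name == "periventricular")
            specs[axis] = pressure_spectrum(tr)
        bin_hz = 1.0 / 2e-3
        assert abs(specs[0].dominant_peak - specs[1].dominant_peak) < bin_hz

    def test_amplitude_differs_with_direction(self, two_direction_runs):
        amps = {}
        for axis, res in two_direction_runs.items():
            tr = next(t for t in res.traces if t.name == "periventricular")
            sp = pressure_spectrum(tr)
            amps[axis] = sp.amplitude_at(sp.dominant_peak)
        assert amps[0] != pytest.approx(amps[1], rel=0.02)


def test_nearest_resample_identity_and_halving():
    v = np.arange(8 * 6 * 4).reshape(8, 6, 4)
    assert np.array_equal(nearest_resample(v, 1.0, 1.0), v)
    half = nearest_resample(v, 1.0, 2.0)
    assert half.shape == (4, 3, 2)
    assert half[0, 0, 0] == v[1, 1, 1]


def test_probe_trace_requires_uniform_sampling():
    with pytest.raises(ValueError, match="uniform"):
        ProbeTrace("p", np.array([0.0, 1.0, 3.0, 4.0]), np.zeros(4))
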