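"""Thermoelastic pressure-wave solvers for the pulse-heated head.

Rapid heating (pulse duration tau_d short against the acoustic transit
time tau_c = a / c_B of the head) leaves the tissue no time to expand:
the heated region is inertially confined and acquires a thermal stress
sigma = -K * beta * dT, which then relaxes by radiating pressure waves.
In a quasi-spherical head the inward-running waves converge and amplify
tensile (negative) pressure near the centre — stress focusing.  For slow
heating (tau_d >> tau_c) the body expands quasi-statically and only the
strain-incompatible part of the thermal field (second order and higher in
position) leaves residual stress.

Two solvers share the same staggered (pressure-velocity) leapfrog core:

* :func:`solve_spherical` — 1D spherically symmetric, used for modal
  analysis (microwave-auditory frequencies) and limit checks;
* :func:`solve_cartesian` — coarse 3D heterogeneous solver on the voxel
  phantom, with a rigid-skull or stiff-fluid-skull boundary, probe traces,
  a running minimum-pressure map and principal-strain tracking.

Brain, CSF and ventricles are treated as fluid-like acoustic media: the
shear modulus of brain tissue is orders of magnitude below its bulk
modulus, so the pressure response dominates.  Bone thermal expansion is
neglected (its expansion coefficient and SAR are both far smaller than
soft tissue's).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .phantom import PhantomGrid, BRAIN_FLUID, SKULL
from .thermal import TemperatureLoad

__all__ = [
    "AcousticMedium",
    "ProbeTrace",
    "SphericalWaveResult",
    "CartesianWaveResult",
    "characteristic_time",
    "inertial_confinement_pressure",
    "solve_spherical",
    "solve_cartesian",
    "nearest_resample",
]


def characteristic_time(a: float, c_bulk: float) -> float:
    """Acoustic transit time tau_c = a / c_bulk of a sphere of radius a."""
    if a < 0 or c_bulk <= 0:
        raise ValueError("radius must be >= 0 and wave speed > 0")
    return a / c_bulk


def inertial_confinement_pressure(K: float, beta: float, delta_T: float) -> float:
    """Instantaneous-heating stress magnitude K * beta * dT (Pa)."""
    if K <= 0 or beta <= 0:
        raise ValueError("K and beta must be positive")
    return K * beta * delta_T


@dataclass
class AcousticMedium:
    """Fluid-like acoustic medium: density, bulk modulus and volumetric
    thermal expansion (beta = 3 * alpha), scalar or per-cell."""

    rho: np.ndarray | float
    K: np.ndarray | float
    beta: np.ndarray | float

    def c_bulk(self):
        return np.sqrt(np.asarray(self.K) / np.asarray(self.rho))


@dataclass
class ProbeTrace:
    """Uniformly sampled pressure history at a named probe."""

    name: str
    times: np.ndarray
    pressure: np.ndarray

    def __post_init__(self):
        if len(self.times) != len(self.pressure):
            raise ValueError("times and pressure must have equal length")
        if len(self.times) > 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=0):
                raise ValueError("probe sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class SphericalWaveResult:
    traces: list[ProbeTrace]
    times: np.ndarray
    radii: np.ndarray                  # pressure-cell radii
    pressure_history: np.ndarray       # (n_snapshots, n_shells)
    snapshot_times: np.ndarray
    dt: float


@dataclass
class CartesianWaveResult:
    traces: list[ProbeTrace]
    times: np.ndarray
    min_pressure: np.ndarray           # per-voxel min over time (Pa)
    mps_times: np.ndarray
    mps_series: np.ndarray             # global max principal log strain
    strain_rate_series: np.ndarray     # global max principal strain rate
    solved_mask: np.ndarray
    spacing: float
    dt: float

    @property
    def mps(self) -> float:
        return float(self.mps_series.max(initial=0.0))

    @property
    def max_strain_rate(self) -> float:
        return float(self.strain_rate_series.max(initial=0.0))


# ---------------------------------------------------------------------------
# 1D spherically symmetric solver
# ---------------------------------------------------------------------------

def solve_spherical(
    medium: AcousticMedium,
    load: TemperatureLoad,
    duration: float,
    probe_radii: dict[str, float] | None = None,
    boundary: str = "pressure_release",
    n_shells: int = 256,
    radius: float | None = None,
    cfl: float = 0.9,
    snapshot_stride: int = 8,
) -> SphericalWaveResult:
    """Thermoelastic pressure waves in a radially layered sphere.

    Pressure lives at shell centres r_i = (i + 1/2) dr, radial velocity at
    shell faces r = i dr with v(0) = 0 (regularity at the origin).  The
    outer boundary is either ``pressure_release`` (p = 0, free surface) or
    ``rigid`` (v = 0).  ``load.delta_T`` may be a scalar or a radial
    profile of length ``n_shells``; the temperature follows the linear
    ramp of duration ``load.tau_d``.
    """
    if boundary not in ("pressure_release", "rigid"):
        raise ValueError(f"unknown boundary {boundary!r}")
    rho = np.broadcast_to(np.asarray(medium.rho, float), (n_shells,)).copy()
    K = np.broadcast_to(np.asarray(medium.K, float), (n_shells,)).copy()
    beta = np.broadcast_to(np.asarray(medium.beta, float), (n_shells,)).copy()
    dT = np.broadcast_to(np.asarray(load.delta_T, float), (n_shells,)).copy()
    if radius is None:
        raise ValueError("radius of the sphere is required")
    dr = radius / n_shells
    c = np.sqrt(K / rho)
    dt = cfl * dr / c.max()
    n_steps = int(np.ceil(duration / dt))

    r_face = np.arange(n_shells + 1) * dr
    r_cell = (np.arange(n_shells) + 0.5) * dr
    rho_face = np.empty(n_shells + 1)
    rho_face[1:-1] = 0.5 * (rho[1:] + rho[:-1])
    rho_face[0] = rho[0]
    rho_face[-1] = rho[-1]

    probe_radii = probe_radii or {}
    probe_idx = {}
    for name, pr in probe_radii.items():
        if not (0 <= pr <= radius):
            raise ValueError(f"probe {name!r} radius {pr} outside the sphere")
        probe_idx[name] = min(int(pr / dr), n_shells - 1)

    p = np.zeros(n_shells)
    v = np.zeros(n_shells + 1)
    times = (np.arange(n_steps) + 1) * dt
    records = {name: np.empty(n_steps) for name in probe_idx}
    n_snap = n_steps // snapshot_stride + 1
    history = np.zeros((n_snap, n_shells))
    snap_times = np.zeros(n_snap)
    rf2 = r_face**2
    rc2 = r_cell**2

    def ramp(t):
        return min(t / load.tau_d, 1.0) if load.tau_d > 0 else 1.0

    t = 0.0
    isnap = 0
    for step in range(n_steps):
        # velocity update (faces 1..N-1), origin fixed
        v[1:-1] -= dt / rho_face[1:-1] * (p[1:] - p[:-1]) / dr
        if boundary == "rigid":
            v[-1] = 0.0
        else:
            p_ghost = -p[-1]  # antisymmetric ghost puts p = 0 at r = a
            v[-1] -= dt / rho_face[-1] * (p_ghost - p[-1]) / dr
        # pressure update with thermal forcing
        div = (rf2[1:] * v[1:] - rf2[:-1] * v[:-1]) / (rc2 * dr)
        dT_inc = (ramp(t + dt) - ramp(t)) * dT
        p += -dt * K * div + K * beta * dT_inc
        t += dt
        for name, idx in probe_idx.items():
            records[name][step] = p[idx]
        if step % snapshot_stride == 0:
            history[isnap] = p
            snap_times[isnap] = t
            isnap += 1

    traces = [ProbeTrace(name, times, records[name]) for name in records]
    return SphericalWaveResult(
        traces=traces, times=times, radii=r_cell,
        pressure_history=history[:isnap], snapshot_times=snap_times[:isnap],
        dt=dt,
    )


# ---------------------------------------------------------------------------
# 3D Cartesian solver
# ---------------------------------------------------------------------------

def nearest_resample(volume: np.ndarray, src_spacing: float,
                     dst_spacing: float) -> np.ndarray:
    """Nearest-neighbour regridding of a voxel volume to a new spacing."""
    if src_spacing == dst_spacing:
        return volume.copy()
    shape = tuple(
        max(int(np.floor(n * src_spacing / dst_spacing)), 1)
        for n in volume.shape
    )
    idx = [
        np.minimum(
            ((np.arange(m) + 0.5) * dst_spacing / src_spacing).astype(int),
            n - 1,
        )
        for m, n in zip(shape, volume.shape)
    ]
    return volume[np.ix_(*idx)]


def _prop(labels: np.ndarray, table, attr: str, default: float = 0.0):
    """Label volume -> per-voxel TissueSpec attribute map."""
    lut = np.full(int(labels.max()) + 1, default, dtype=np.float64)
    for lab, spec in table.items():
        if lab <= labels.max():
            lut[lab] = getattr(spec, attr)
    return lut[labels]


def _max_eig_sym3(sxx, syy, szz, sxy, sxz, syz):
    """Largest eigenvalue of symmetric 3x3 tensors, vectorised
    (trigonometric closed form)."""
    q = (sxx + syy + szz) / 3.0
    p1 = sxy**2 + sxz**2 + syz**2
    p2 = (sxx - q) ** 2 + (syy - q) ** 2 + (szz - q) ** 2 + 2.0 * p1
    p = np.sqrt(np.maximum(p2, 0.0) / 6.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        bxx = np.where(p > 0, (sxx - q) / p, 0.0)
        byy = np.where(p > 0, (syy - q) / p, 0.0)
        bzz = np.where(p > 0, (szz - q) / p, 0.0)
        bxy = np.where(p > 0, sxy / p, 0.0)
        bxz = np.where(p > 0, sxz / p, 0.0)
        byz = np.where(p > 0, syz / p, 0.0)
    detb = (bxx * (byy * bzz - byz**2) - bxy * (bxy * bzz - byz * bxz)
            + bxz * (bxy * byz - byy * bxz))
    phi = np.arccos(np.clip(detb / 2.0, -1.0, 1.0)) / 3.0
    return q + 2.0 * p * np.cos(phi)


def solve_cartesian(
    phantom: PhantomGrid,
    load: TemperatureLoad,
    duration: float,
    probes: dict[str, tuple[int, int, int]] | None = None,
    skull: str = "rigid",
    spacing: float | None = None,
    cfl: float = 0.9,
    strain_stride: int = 5,
) -> CartesianWaveResult:
    """Heterogeneous 3D thermoelastic pressure-wave solve on the phantom.

    The intracranial fluids (CSF, gray, white matter) are the solved
    acoustic region.  ``skull="rigid"`` clamps the normal velocity at the
    skull (zero-flux confinement); ``skull="stiff_fluid"`` includes the
    skull as a dense, stiff, non-expanding fluid with a free outer surface.
    ``spacing`` (default: the phantom's) resamples labels and load onto a
    coarser wave grid by nearest neighbour.

    Returns probe traces, the running per-voxel minimum pressure, and the
    time series of the global maximum principal (logarithmic) strain and
    strain rate.
    """
    if skull not in ("rigid", "stiff_fluid"):
        raise ValueError(f"unknown skull treatment {skull!r}")
    probes = dict(probes) if probes is not None else dict(phantom.probes)

    labels = phantom.labels
    dT = np.asarray(load.delta_T, float)
    if dT.shape != labels.shape:
        raise ValueError("load not co-registered with phantom")
    dx = phantom.spacing
    if spacing is not None and spacing != phantom.spacing:
        scale = phantom.spacing / spacing
        labels = nearest_resample(labels, phantom.spacing, spacing)
        dT = nearest_resample(dT, phantom.spacing, spacing)
        probes = {
            name: tuple(
                min(int(round(i * scale)), n - 1)
                for i, n in zip(idx, labels.shape)
            )
            for name, idx in probes.items()
        }
        dx = spacing

    fluid = np.isin(labels, BRAIN_FLUID)
    solved = fluid | (labels == SKULL) if skull == "stiff_fluid" else fluid
    if not solved.any():
        raise ValueError("no solvable acoustic region in phantom")
    for name, idx in probes.items():
        if not fluid[idx]:
            raise ValueError(f"probe {name!r} at {idx} outside brain region")

    rho = np.where(solved, _prop(labels, phantom.tissue_table, "rho", 1.0), 1.0)
    K = np.where(solved, _prop(labels, phantom.tissue_table, "K", 1.0), 1.0)
    # thermal expansion drives white matter, gray matter and CSF only;
    # bone expansion is neglected even in stiff-fluid mode
    beta = np.where(fluid, 3.0 * _prop(labels, phantom.tissue_table, "alpha"), 0.0)
    dT = np.where(fluid, dT, 0.0)

    z = np.sqrt(rho * K)[solved]
    if z.max() / z.min() > 100.0:
        warnings.warn(
            f"acoustic impedance contrast {z.max() / z.min():.0f} > 100; "
            f"the explicit scheme may be inaccurate at the interfaces",
            stacklevel=2,
        )

    c_max = float(np.sqrt(K / rho)[solved].max())
    dt = cfl * dx / (c_max * np.sqrt(3.0))
    n_steps = int(np.ceil(duration / dt))

    nx, ny, nz = labels.shape
    p = np.zeros((nx, ny, nz))
    vx = np.zeros((nx + 1, ny, nz))
    vy = np.zeros((nx, ny + 1, nz))
    vz = np.zeros((nx, ny, nz + 1))
    ux = np.zeros_like(vx)
    uy = np.zeros_like(vy)
    uz = np.zeros_like(vz)

    if skull == "rigid":
        mx = solved[:-1] & solved[1:]
        my = solved[:, :-1] & solved[:, 1:]
        mz = solved[:, :, :-1] & solved[:, :, 1:]
    else:
        mx = solved[:-1] | solved[1:]
        my = solved[:, :-1] | solved[:, 1:]
        mz = solved[:, :, :-1] | solved[:, :, 1:]
    rfx = np.where(mx, 2.0 / (rho[:-1] + rho[1:]), 0.0)
    rfy = np.where(my, 2.0 / (rho[:, :-1] + rho[:, 1:]), 0.0)
    rfz = np.where(mz, 2.0 / (rho[:, :, :-1] + rho[:, :, 1:]), 0.0)

    Kdt = dt * K
    forcing = K * beta * dT  # per unit ramp fraction

    times = (np.arange(n_steps) + 1) * dt
    records = {name: np.empty(n_steps) for name in probes}
    min_p = np.zeros_like(p)
    mps_t, mps_vals, rate_vals = [], [], []
    tau_d = load.tau_d

    def ramp(t):
        return min(t / tau_d, 1.0) if tau_d > 0 else 1.0

    inv_dx = 1.0 / dx
    t = 0.0
    for step in range(n_steps):
        # velocity update on active faces (p = 0 outside the solved region)
        vx[1:-1] -= dt * rfx * (p[1:] - p[:-1]) * inv_dx
        vy[:, 1:-1] -= dt * rfy * (p[:, 1:] - p[:, :-1]) * inv_dx
        vz[:, :, 1:-1] -= dt * rfz * (p[:, :, 1:] - p[:, :, :-1]) * inv_dx
        ux += vx * dt
        uy += vy * dt
        uz += vz * dt
        # pressure update with thermal forcing
        div = ((vx[1:] - vx[:-1]) + (vy[:, 1:] - vy[:, :-1])
               + (vz[:, :, 1:] - vz[:, :, :-1])) * inv_dx
        dramp = ramp(t + dt) - ramp(t)
        p -= Kdt * div
        if dramp > 0:
            p += forcing * dramp
        p[~solved] = 0.0
        t += dt
        np.minimum(min_p, p, out=min_p)
        for name, idx in probes.items():
            records[name][step] = p[idx]
        if step % strain_stride == 0 or step == n_steps - 1:
            mps_t.append(t)
            mps_vals.append(_principal_from_staggered(ux, uy, uz, solved,
                                                      inv_dx, log=True))
            rate_vals.append(_principal_from_staggered(vx, vy, vz, solved,
                                                       inv_dx, log=False))
        if step % 200 == 0 and not np.isfinite(p).all():
            raise FloatingPointError("3D wave solve diverged")

    traces = [ProbeTrace(name, times, rec) for name, rec in records.items()]
    return CartesianWaveResult(
        traces=traces, times=times, min_pressure=min_p,
        mps_times=np.asarray(mps_t), mps_series=np.asarray(mps_vals),
        strain_rate_series=np.asarray(rate_vals), solved_mask=solved,
        spacing=dx, dt=dt,
    )


def _principal_from_staggered(fx, fy, fz, solved, inv_dx, log=False):
    """Global max principal value of the symmetric gradient of a staggered
    vector field (displacement -> strain, velocity -> strain rate)."""
    cx = 0.5 * (fx[1:] + fx[:-1])
    cy = 0.5 * (fy[:, 1:] + fy[:, :-1])
    cz = 0.5 * (fz[:, :, 1:] + fz[:, :, :-1])
    sxx = (fx[1:] - fx[:-1]) * inv_dx
    syy = (fy[:, 1:] - fy[:, :-1]) * inv_dx
    szz = (fz[:, :, 1:] - fz[:, :, :-1]) * inv_dx
    gxy = np.gradient(cx, axis=1) * inv_dx
    gyx = np.gradient(cy, axis=0) * inv_dx
    gxz = np.gradient(cx, axis=2) * inv_dx
    gzx = np.gradient(cz, axis=0) * inv_dx
    gyz = np.gradient(cy, axis=2) * inv_dx
    gzy = np.gradient(cz, axis=1) * inv_dx
    sxy = 0.5 * (gxy + gyx)
    sxz = 0.5 * (gxz + gzx)
    syz = 0.5 * (gyz + gzy)
    eig = _max_eig_sym3(sxx, syy, szz, sxy, sxz, syz)[solved]
    m = float(eig.max(initial=0.0))
    return float(np.log1p(m)) if log else m
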