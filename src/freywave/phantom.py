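"""Synthetic voxel head phantoms and tissue property tables.

The phantom is a layered sphere or ellipsoid standing in for a segmented
MRI head model: concentric shells labelled outside-in as skin, skull,
cerebrospinal fluid (CSF), gray matter and white matter, with an optional
CSF-filled ventricle inclusion near the centre.  Per-tissue physical
constants (dielectric, thermal, acoustic) live in one table in this module
so that every downstream number can be traced to a named constant.

Coordinate convention: 0-based voxel indices, axis order
(x = left-right, y = posterior-anterior, z = inferior-superior).
A plane wave propagating along +y is a "frontal exposure", along +x a
"side exposure"; the electric field is always z-polarised (vertical).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import nibabel as nib

__all__ = [
    "TissueSpec",
    "PhantomGrid",
    "build_layered_head",
    "tissue_property_table",
    "LABELS",
    "DEFAULT_LAYERS",
]

# ---------------------------------------------------------------------------
# Tissue labels
# ---------------------------------------------------------------------------

VACUUM, SKIN, SKULL, CSF, GRAY, WHITE = 0, 1, 2, 3, 4, 5

LABELS = {
    "vacuum": VACUUM,
    "skin": SKIN,
    "skull": SKULL,
    "csf": CSF,
    "gray": GRAY,
    "white": WHITE,
}

#: Labels counted as "intracranial contents" for dosimetry summaries.
INTRACRANIAL = (CSF, GRAY, WHITE)
#: Labels that are mechanically fluid-like and thermally expanding.
BRAIN_FLUID = (CSF, GRAY, WHITE)


@dataclass(frozen=True)
class TissueSpec:
    """Physical constants of one tissue at one carrier frequency.

    Parameters
    ----------
    name : tissue label
    eps_r : relative permittivity (dimensionless)
    sigma : electrical conductivity (S/m)
    rho : mass density (kg/m^3)
    cp : specific heat capacity (J kg^-1 K^-1)
    alpha : linear thermal expansion coefficient (1/degC)
    c_bulk : bulk (pressure) wave speed (m/s)
    K : bulk modulus (Pa); must satisfy K = rho * c_bulk**2
    """

    name: str
    eps_r: float
    sigma: float
    rho: float
    cp: float
    alpha: float
    c_bulk: float
    K: float = field(default=0.0)

    def __post_init__(self):
        if self.K == 0.0:
            object.__setattr__(self, "K", self.rho * self.c_bulk**2)
        for attr in ("eps_r", "rho", "cp", "c_bulk", "K"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}: {attr} must be positive")
        if self.sigma < 0:
            raise ValueError(f"{self.name}: sigma must be >= 0")
        if self.alpha < 0:
            raise ValueError(f"{self.name}: alpha must be >= 0")
        if abs(self.K - self.rho * self.c_bulk**2) > 1e-9 * self.K:
            raise ValueError(
                f"{self.name}: bulk modulus K inconsistent with rho*c_bulk^2"
            )

    @property
    def beta(self) -> float:
        """Volumetric thermal expansion coefficient, 3*alpha (1/degC)."""
        return 3.0 * self.alpha


# ---------------------------------------------------------------------------
# Property tables
# ---------------------------------------------------------------------------
# Dielectric constants: literature-typical (Gabriel-style parametric model)
# values tabulated at anchor frequencies within the supported 0.4-3 GHz band
# and log-frequency interpolated in between.  Single-frequency lookup only;
# no Debye/Cole-Cole dispersion model is fitted.

_FREQ_ANCHORS_GHZ = np.array([0.4, 0.9, 1.0, 1.8, 2.45, 3.0])

# rows: (eps_r at anchors), (sigma S/m at anchors)
_DIELECTRICS = {
    "skin": (
        [46.8, 41.4, 40.9, 38.9, 38.0, 37.5],
        [0.69, 0.87, 0.90, 1.18, 1.46, 1.74],
    ),
    "skull": (
        [13.1, 12.5, 12.4, 11.9, 11.4, 11.1],
        [0.09, 0.14, 0.16, 0.28, 0.39, 0.51],
    ),
    "csf": (
        [70.6, 68.6, 68.4, 67.2, 66.2, 65.5],
        [2.25, 2.41, 2.46, 2.92, 3.46, 4.00],
    ),
    "gray": (
        [57.4, 52.7, 52.3, 50.8, 48.9, 48.2],
        [0.74, 0.94, 0.98, 1.28, 1.81, 2.20],
    ),
    "white": (
        [42.0, 38.9, 38.6, 37.2, 36.2, 35.6],
        [0.45, 0.59, 0.62, 0.83, 1.21, 1.50],
    ),
}

# Frequency-independent thermal / acoustic / mechanical constants.
# Brain bulk wave speed 1450 m/s (soft-tissue literature value); bone linear
# thermal expansion 0.27e-4 /degC; soft tissue volumetric expansion beta =
# 3*alpha ~ 3.6e-4 /degC (water near body temperature), hence alpha = 1.2e-4.
# rho/cp are typical tissue-database values; brain cp defaults to 3600.
#                    rho     cp     alpha     c_bulk
_THERMOACOUSTIC = {
    "vacuum": (1.2, 1005.0, 0.0, 343.0),   # modelled as air
    "skin":   (1109.0, 3391.0, 1.2e-4, 1540.0),
    "skull":  (1908.0, 1313.0, 0.27e-4, 2900.0),
    "csf":    (1007.0, 4096.0, 1.2e-4, 1480.0),
    "gray":   (1045.0, 3600.0, 1.2e-4, 1450.0),
    "white":  (1041.0, 3600.0, 1.2e-4, 1450.0),
}

FREQ_MIN_HZ = 0.4e9
FREQ_MAX_HZ = 3.0e9


def tissue_property_table(frequency: float) -> dict[int, TissueSpec]:
    """Per-tissue constants at one carrier frequency, keyed by voxel label.

    Dielectric values are interpolated in log-frequency between tabulated
    anchors; thermal, acoustic and mechanical constants are
    frequency-independent.

    Parameters
    ----------
    frequency : carrier frequency in Hz; must lie in [0.4, 3] GHz.
    """
    if not (FREQ_MIN_HZ <= frequency <= FREQ_MAX_HZ):
        raise ValueError(
            f"frequency {frequency:.3g} Hz outside supported band "
            f"[{FREQ_MIN_HZ:.1e}, {FREQ_MAX_HZ:.1e}] Hz"
        )
    logf = np.log10(frequency / 1e9)
    log_anchors = np.log10(_FREQ_ANCHORS_GHZ)
    table: dict[int, TissueSpec] = {}
    for name, label in LABELS.items():
        rho, cp, alpha, c_bulk = _THERMOACOUSTIC[name]
        if name == "vacuum":
            eps_r, sigma = 1.0, 0.0
        else:
            eps_tab, sig_tab = _DIELECTRICS[name]
            eps_r = float(np.interp(logf, log_anchors, eps_tab))
            sigma = float(np.interp(logf, log_anchors, sig_tab))
        table[label] = TissueSpec(
            name=name, eps_r=eps_r, sigma=sigma, rho=rho, cp=cp,
            alpha=alpha, c_bulk=c_bulk,
        )
    return table


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

#: Default shell thicknesses (m), outside-in.  With a 0.17 m head the brain
#: compartment spans 0.17 - 2*(0.003 + 0.007 + 0.003) = 0.144 m; dropping the
#: skin layer gives the 0.15 m brain sphere used in idealised runs.
DEFAULT_LAYERS = {"skin": 3e-3, "skull": 7e-3, "csf": 3e-3}

#: Default cortical (gray matter) shell thickness inside the CSF (m).
DEFAULT_GRAY_THICKNESS = 10e-3

#: Left-right and inferior-superior semi-axis ratios of the ellipsoid head
#: relative to the anterior-posterior semi-axis.
ELLIPSOID_RATIOS = (0.85, 1.0, 1.0)  # (x, y, z); y is anterior-posterior


@dataclass
class PhantomGrid:
    """Voxelised multi-tissue phantom.

    Attributes
    ----------
    spacing : voxel edge length (m); cubic voxels
    labels : 3D int array of tissue labels, axis order (x, y, z)
    tissue_table : label -> :class:`TissueSpec`
    head_length : anterior-posterior extent 2a of the head (m)
    probes : probe name -> (i, j, k) voxel index; frontal, periventricular
        and occipital probes lie on the midline inside brain tissue
    """

    spacing: float
    labels: np.ndarray
    tissue_table: dict[int, TissueSpec]
    head_length: float
    probes: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self):
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.tissue_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from tissue_table")
        body = self.labels > 0
        if body.any():
            ys = np.nonzero(body.any(axis=(0, 2)))[0]
            extent = (ys[-1] - ys[0] + 1) * self.spacing
            if abs(extent - self.head_length) > 2 * self.spacing:
                raise ValueError(
                    f"head_length {self.head_length} inconsistent with labelled "
                    f"anterior-posterior extent {extent:.4f}"
                )
        for name, idx in self.probes.items():
            if self.labels[idx] not in BRAIN_FLUID:
                raise ValueError(f"probe {name!r} at {idx} not in brain tissue")

    # -- derived fields ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def body_mask(self) -> np.ndarray:
        return self.labels > 0

    def brain_mask(self) -> np.ndarray:
        return np.isin(self.labels, BRAIN_FLUID)

    def property_volume(self, attr: str, default: float = 0.0) -> np.ndarray:
        """Per-voxel map of one :class:`TissueSpec` attribute."""
        lut = np.full(int(self.labels.max()) + 1, default, dtype=np.float64)
        for label, spec in self.tissue_table.items():
            if label <= self.labels.max():
                lut[label] = getattr(spec, attr)
        return lut[self.labels]

    # -- I/O ---------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the label volume as NIfTI plus a JSON sidecar."""
        path = Path(path)
        affine = np.diag([self.spacing * 1e3] * 3 + [1.0])  # NIfTI in mm
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), path)
        sidecar = {
            "spacing_m": self.spacing,
            "head_length_m": self.head_length,
            "probes": {k: list(v) for k, v in self.probes.items()},
            "tissue_table": {
                str(label): asdict(spec) for label, spec in self.tissue_table.items()
            },
        }
        sidecar_path = path.with_suffix("").with_suffix("")  # strip .nii.gz
        Path(str(sidecar_path) + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )

    @classmethod
    def load(cls, path: str | Path) -> "PhantomGrid":
        path = Path(path)
        img = nib.load(path)
        labels = np.asarray(img.dataobj).astype(np.int16)
        sidecar_path = Path(str(path.with_suffix("").with_suffix("")) + ".json")
        meta = json.loads(sidecar_path.read_text())
        table = {
            int(k): TissueSpec(**v) for k, v in meta["tissue_table"].items()
        }
        probes = {k: tuple(v) for k, v in meta["probes"].items()}
        return cls(
            spacing=meta["spacing_m"],
            labels=labels,
            tissue_table=table,
            head_length=meta["head_length_m"],
            probes=probes,
        )


def _normalized_radius(shape, spacing, semi_axes):
    """Per-voxel normalised ellipsoid radius about the grid centre
    (<=1 means inside).  Coordinates are formed symmetrically in index
    space so mirror symmetry holds exactly in floating point."""
    ax = [(np.arange(n) - (n - 1) / 2.0) * spacing for n in shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    a, b, c = semi_axes
    return np.sqrt((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2)


def build_layered_head(
    outer_diameter: float = 0.17,
    layer_thicknesses: dict[str, float] | None = None,
    spacing: float = 2e-3,
    shape: str = "ellipsoid",
    gray_thickness: float = DEFAULT_GRAY_THICKNESS,
    ventricles: bool = True,
    frequency: float = 1e9,
    margin_voxels: int = 2,
) -> PhantomGrid:
    """Build a layered sphere/ellipsoid head phantom.

    The outer surface has anterior-posterior diameter ``outer_diameter``
    (the head length 2a).  Shells are labelled outside-in skin, skull, CSF;
    the remaining interior is gray matter (a shell of ``gray_thickness``)
    around a white-matter core, optionally with a CSF-labelled ellipsoidal
    ventricle inclusion at the centre.

    Parameters
    ----------
    outer_diameter : anterior-posterior head length (m)
    layer_thicknesses : shell thickness per layer name among
        {"skin", "skull", "csf"} (m); omitted layers are skipped
    spacing : cubic voxel edge length (m)
    shape : "sphere" or "ellipsoid" (ellipsoid narrows left-right by 15%)
    gray_thickness : cortical shell thickness (m)
    ventricles : include a CSF-labelled central ventricle inclusion
    frequency : carrier frequency (Hz) for the attached tissue table
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if shape not in ("sphere", "ellipsoid"):
        raise ValueError(f"unsupported shape {shape!r}")
    layers = DEFAULT_LAYERS if layer_thicknesses is None else layer_thicknesses
    unknown = set(layers) - {"skin", "skull", "csf"}
    if unknown:
        raise ValueError(f"unknown layer names {sorted(unknown)}")
    a_y = outer_diameter / 2.0
    total_shell = sum(layers.values())
    if total_shell >= a_y:
        raise ValueError("layer thicknesses exceed the outer radius")
    thinnest = min([t for t in layers.values() if t > 0], default=a_y)
    if spacing > thinnest:
        raise ValueError(
            f"spacing {spacing} m too coarse to resolve the thinnest layer "
            f"({thinnest} m); use spacing <= {thinnest} m"
        )

    rx, ry, rz = (1.0, 1.0, 1.0) if shape == "sphere" else ELLIPSOID_RATIOS
    semi = np.array([rx * a_y, ry * a_y, rz * a_y])
    n = np.ceil(2 * semi / spacing).astype(int) + 2 * margin_voxels + 1
    shape3 = tuple(int(v) for v in n)

    labels = np.zeros(shape3, dtype=np.int16)
    # Outside-in: each surface k is the ellipsoid shrunk by the cumulative
    # shell thickness; assign the layer label where the voxel is inside
    # surface k but outside surface k+1.
    order = [("skin", SKIN), ("skull", SKULL), ("csf", CSF)]
    cum = 0.0
    rho_outer = _normalized_radius(shape3, spacing, semi)
    inside_prev = rho_outer <= 1.0
    for name, label in order:
        t = layers.get(name, 0.0)
        if t <= 0:
            continue
        cum += t
        inner = _normalized_radius(shape3, spacing, semi - cum) <= 1.0
        labels[inside_prev & ~inner] = label
        inside_prev = inner
    # gray shell then white core
    inner_gray = (
        _normalized_radius(shape3, spacing, semi - cum - gray_thickness)
        <= 1.0
    )
    labels[inside_prev & ~inner_gray] = GRAY
    labels[inner_gray] = WHITE

    if ventricles:
        vent_semi = np.array([10e-3, 20e-3, 10e-3])
        vent = _normalized_radius(shape3, spacing, vent_semi) <= 1.0
        labels[vent & (labels == WHITE)] = CSF

    table = tissue_property_table(frequency)
    probes = _default_probes(labels, spacing)
    return PhantomGrid(
        spacing=spacing,
        labels=labels,
        tissue_table=table,
        head_length=outer_diameter,
        probes=probes,
    )


def _default_probes(labels: np.ndarray, spacing: float):
    """Midline probes at 25% (frontal), 50% (periventricular) and 75%
    (occipital) of the brain's anterior-posterior extent.

    The frontal probe sits nearest the entry face of a +y ("frontal")
    exposure.  Probes snap to the closest brain-tissue voxel on the midline.
    """
    brain = np.isin(labels, BRAIN_FLUID)
    if not brain.any():
        return {}
    i_mid = labels.shape[0] // 2
    k_mid = labels.shape[2] // 2
    ys = np.nonzero(brain.any(axis=(0, 2)))[0]
    y0, y1 = ys[0], ys[-1]
    probes = {}
    for name, frac in [("frontal", 0.25), ("periventricular", 0.5),
                       ("occipital", 0.75)]:
        j = int(round(y0 + frac * (y1 - y0)))
        idx = _snap_to_mask(brain, (i_mid, j, k_mid))
        probes[name] = idx
    return probes


def _snap_to_mask(mask: np.ndarray, idx):
    """Nearest True voxel to idx (searched on the same midline column first)."""
    if mask[idx]:
        return tuple(int(v) for v in idx)
    i, j, k = idx
    col = np.nonzero(mask[:, j, :])
    if col[0].size:
        d2 = (col[0] - i) ** 2 + (col[1] - k) ** 2
        m = int(np.argmin(d2))
        return (int(col[0][m]), int(j), int(col[1][m]))
    pts = np.argwhere(mask)
    d2 = ((pts - np.array(idx)) ** 2).sum(axis=1)
    return tuple(int(v) for v in pts[int(np.argmin(d2))])
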