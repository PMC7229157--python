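"""Synthetic dual-wavelength photoacoustic phantoms with known ground truth.

Real breast PA/US volumes from the clinical system this pipeline targets are
not publicly available, so validation rests on phantoms: voxel grids of oxy-
and deoxy-haemoglobin concentration containing an ellipsoidal tumour and
capsule-shaped vessels, forward-projected into two-wavelength PA slice
stacks with a depth-decaying fluence, per-frame laser-energy jitter and
additive Gaussian noise.  Because the generating SO2 field is known exactly,
every downstream stage can be checked by parameter recovery.

The default acquisition geometry emulates a linear-probe sweep: 0.2 mm slice
steps over a 4 cm scan, with the row axis pointing into the tissue (depth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .exceptions import ConfigurationError, GeometryError
from .roi3d import ContourStack, Ellipsoid, SliceContours, VoxelMask
from .unmixing import DualWavelengthVolume, ExtinctionTable

logger = logging.getLogger(__name__)

__all__ = [
    "VesselSegment",
    "PhantomSpec",
    "LabelledPhantom",
    "ForwardModelConfig",
    "build_phantom",
    "forward_project",
    "generate_cohort",
    "SyntheticCase",
]

#: Default grid: 200 slices x 0.2 mm sweep = 4 cm; 36 mm depth, 38.4 mm width.
DEFAULT_GRID_SHAPE = (200, 120, 128)
DEFAULT_VOXEL_SIZE = (0.2, 0.3, 0.3)


@dataclass(frozen=True)
class VesselSegment:
    """A capsule (cylinder with hemispherical caps) of whole blood.

    Endpoints in world (z, y, x) mm; concentration is total haemoglobin in
    mol/L split by the SO2 fraction.
    """

    p0: tuple
    p1: tuple
    radius: float
    so2: float
    thb: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ConfigurationError("vessel radius must be positive")
        if not 0.0 <= self.so2 <= 1.0:
            raise ConfigurationError("vessel SO2 must lie in [0, 1]")
        if self.thb < 0:
            raise ConfigurationError("vessel haemoglobin must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of a phantom: geometry, tissue classes, noise."""

    grid_shape: tuple = DEFAULT_GRID_SHAPE
    voxel_size: tuple = DEFAULT_VOXEL_SIZE
    tumour_ellipsoid: Ellipsoid | None = None
    vessel_segments: tuple = ()
    tumour_so2: float = 0.70
    tumour_thb: float = 100e-6
    background_thb: float = 20e-6
    background_so2: float = 0.75
    #: optional peri-tumoral shell (between the tumour ellipsoid and its
    #: shell_factor-scaled copy) with its own oxygenation — models the
    #: altered peri-tumoral microvascular environment.  None disables it.
    shell_so2: float | None = None
    shell_thb: float = 40e-6
    shell_factor: float = 1.2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.shell_so2 is not None and not 0.0 <= self.shell_so2 <= 1.0:
            raise ConfigurationError("shell_so2 must lie in [0, 1]")
        if self.shell_thb < 0 or self.shell_factor < 1.0:
            raise ConfigurationError("shell_thb >= 0 and shell_factor >= 1 required")
        for name in ("tumour_so2", "background_so2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("tumour_thb", "background_thb"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.tumour_ellipsoid is not None:
            self._check_inside_grid(self.tumour_ellipsoid)

    def _check_inside_grid(self, e: Ellipsoid):
        extents = (np.array(self.grid_shape) - 1) * np.array(self.voxel_size)
        half = np.sqrt(((e.orientation * e.semi_axes) ** 2).sum(axis=1))
        if np.any(e.center - half < -1e-9) or np.any(e.center + half > extents + 1e-9):
            raise GeometryError("tumour ellipsoid extends outside the grid")

    @property
    def extents_mm(self) -> np.ndarray:
        return (np.array(self.grid_shape) - 1) * np.array(self.voxel_size)


@dataclass
class LabelledPhantom:
    """Voxelized haemoglobin fields with their ground-truth labels."""

    c_hb: np.ndarray        # oxy-haemoglobin, mol/L
    c_dehb: np.ndarray      # deoxy-haemoglobin, mol/L
    tumour_mask: VoxelMask
    contour_stack: ContourStack
    spec: PhantomSpec

    @property
    def truth_so2(self) -> np.ndarray:
        """C_HbO2 / (C_HbO2 + C_Hb); NaN where there is no haemoglobin."""
        total = self.c_hb + self.c_dehb
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.c_hb / total
        out[total == 0] = np.nan
        return out


@dataclass(frozen=True)
class ForwardModelConfig:
    """Physics of the forward projection.

    Fluence is modelled as ``surface_fluence(lambda) * exp(-mu(lambda) * depth)``
    with depth = row coordinate (mm).  The default — equal surface fluence and
    equal attenuation at both wavelengths — encodes the equal-fluence
    approximation under which the two-wavelength ratio estimator is exact;
    unequal values let tests probe its violation.
    """

    grueneisen: float = 1.0
    surface_fluence: dict = field(default_factory=lambda: {750.0: 1.0, 830.0: 1.0})
    effective_attenuation: dict = field(default_factory=lambda: {750.0: 0.0, 830.0: 0.0})
    energy_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.grueneisen <= 0:
            raise ConfigurationError("Grueneisen parameter must be positive")
        if any(v <= 0 for v in self.surface_fluence.values()):
            raise ConfigurationError("surface fluence must be positive")
        if any(v < 0 for v in self.effective_attenuation.values()):
            raise ConfigurationError("attenuation must be >= 0")
        if self.energy_jitter_sd < 0:
            raise ConfigurationError("energy_jitter_sd must be >= 0")


def _voxel_center_grids(spec: PhantomSpec):
    S, R, C = spec.grid_shape
    dz, dy, dx = spec.voxel_size
    z = (np.arange(S) * dz)[:, None, None]
    y = (np.arange(R) * dy)[None, :, None]
    x = (np.arange(C) * dx)[None, None, :]
    return z, y, x


def _capsule_mask(spec: PhantomSpec, seg: VesselSegment) -> np.ndarray:
    """Voxels within ``seg.radius`` of the segment p0-p1 (capsule distance)."""
    z, y, x = _voxel_center_grids(spec)
    p0 = np.asarray(seg.p0, dtype=float)
    p1 = np.asarray(seg.p1, dtype=float)
    d = p1 - p0
    L2 = float(d @ d)
    rz, ry, rx = z - p0[0], y - p0[1], x - p0[2]
    if L2 == 0:
        dist2 = rz * rz + ry * ry + rx * rx
        return dist2 <= seg.radius**2
    t = (rz * d[0] + ry * d[1] + rx * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    qz = rz - t * d[0]
    qy = ry - t * d[1]
    qx = rx - t * d[2]
    return qz * qz + qy * qy + qx * qx <= seg.radius**2


def build_phantom(spec: PhantomSpec, contour_vertices: int = 64) -> LabelledPhantom:
    """Paint concentration fields onto the grid and derive the labels.

    Painting order (later wins on overlap): background, tumour, then vessel
    segments in list order.  The tumour's per-slice boundary polygons are the
    analytic ellipsoid cross-sections, sampled at ``contour_vertices``
    vertices, mimicking the physician contour stack of a real acquisition.
    """
    c_hb = np.full(spec.grid_shape, spec.background_thb * spec.background_so2)
    c_dehb = np.full(spec.grid_shape, spec.background_thb * (1 - spec.background_so2))

    tumour = spec.tumour_ellipsoid
    if tumour is None:
        raise GeometryError("phantom needs a tumour ellipsoid")
    z, y, x = _voxel_center_grids(spec)
    A = tumour.quadratic_form
    u, v, w = z - tumour.center[0], y - tumour.center[1], x - tumour.center[2]
    q = (
        A[0, 0] * u * u + A[1, 1] * v * v + A[2, 2] * w * w
        + 2 * A[0, 1] * u * v + 2 * A[0, 2] * u * w + 2 * A[1, 2] * v * w
    )
    tumour_mask = q <= 1.0
    if not tumour_mask.any():
        raise GeometryError("tumour ellipsoid contains no voxel centres")
    if spec.shell_so2 is not None:
        # scaling every semi-axis by f scales the quadratic form by 1/f^2
        shell = (q <= spec.shell_factor**2) & ~tumour_mask
        c_hb[shell] = spec.shell_thb * spec.shell_so2
        c_dehb[shell] = spec.shell_thb * (1 - spec.shell_so2)
    c_hb[tumour_mask] = spec.tumour_thb * spec.tumour_so2
    c_dehb[tumour_mask] = spec.tumour_thb * (1 - spec.tumour_so2)

    for seg in spec.vessel_segments:
        m = _capsule_mask(spec, seg)
        c_hb[m] = seg.thb * seg.so2
        c_dehb[m] = seg.thb * (1 - seg.so2)

    dz = spec.voxel_size[0]
    slices = []
    for k in range(spec.grid_shape[0]):
        poly = tumour.cross_section(k * dz, n_vertices=max(contour_vertices, 16))
        if poly is not None:
            slices.append(SliceContours(position=k * dz, polygons=[poly]))
    contour_stack = ContourStack(slices=slices)

    return LabelledPhantom(
        c_hb=c_hb,
        c_dehb=c_dehb,
        tumour_mask=VoxelMask(tumour_mask, tuple(spec.voxel_size)),
        contour_stack=contour_stack,
        spec=spec,
    )


def forward_project(
    phantom: LabelledPhantom,
    extinction: ExtinctionTable,
    config: ForwardModelConfig,
) -> DualWavelengthVolume:
    """Project haemoglobin fields into dual-wavelength PA slice stacks.

    Per voxel and wavelength::

        signal = Gamma * F(lambda, depth) * (c_hb * eps_oxy + c_dehb * eps_de)
                 * E_frame / E_nominal + noise

    with ``F = surface_fluence * exp(-mu * depth)``, per-frame energies drawn
    around nominal 1.0 with relative sd ``config.energy_jitter_sd`` (recorded
    in the output, as the real system records pulse energies), and noise a
    centred Gaussian whose sd is ``spec.noise_sd`` times the mean noise-free
    signal of that stack.
    """
    spec = phantom.spec
    wavelengths = sorted(config.surface_fluence)
    for wl in wavelengths:
        extinction.coefficients(wl)  # raises ConfigurationError if missing
        if wl not in config.effective_attenuation:
            raise ConfigurationError(f"no attenuation configured for {wl} nm")

    S, R, _ = spec.grid_shape
    dy = spec.voxel_size[1]
    depth = (np.arange(R) * dy)[None, :, None]  # mm below the probe face

    jitter_rng = np.random.default_rng(config.seed)
    noise_rng = np.random.default_rng(spec.seed)

    stacks, energies = {}, {}
    for wl in wavelengths:
        mu = config.effective_attenuation[wl]
        F = config.surface_fluence[wl] * np.exp(-mu * depth)
        eps_oxy, eps_de = extinction.coefficients(wl)
        clean = config.grueneisen * F * (phantom.c_hb * eps_oxy + phantom.c_dehb * eps_de)
        e_frame = np.ones(S)
        if config.energy_jitter_sd > 0:
            e_frame = 1.0 + config.energy_jitter_sd * jitter_rng.standard_normal(S)
            e_frame = np.clip(e_frame, 0.05, None)
        signal = clean * e_frame[:, None, None]
        if spec.noise_sd > 0:
            sd = spec.noise_sd * float(clean.mean())
            signal = signal + sd * noise_rng.standard_normal(signal.shape)
        stacks[wl] = signal
        energies[wl] = e_frame
    return DualWavelengthVolume(
        stacks=stacks,
        frame_energies=energies,
        voxel_size=tuple(spec.voxel_size),
        meta={
            "slice_step_mm": spec.voxel_size[0],
            "sweep_length_mm": spec.voxel_size[0] * (S - 1),
            "energy_normalized": False,
        },
    )


@dataclass
class SyntheticCase:
    """One simulated patient: volume, contours, label and the generating truth."""

    case_id: str
    group: str
    size_mm: float
    volume: DualWavelengthVolume
    contours: ContourStack
    truth_tumour_so2: float
    truth_vessel_so2: float
    spec: PhantomSpec


# Group-level regional SO2 (mean, sd as fractions).  Malignant tumours sit
# ~7.7 points below benign inside the tumour and ~4.9 points below benign in
# the peri-tumoral vessels, with a few points of biological spread.
DEFAULT_GROUP_SO2 = {"benign": (0.785, 0.03), "malignant": (0.708, 0.03)}
DEFAULT_SURROUNDING_SO2 = {"benign": (0.785, 0.03), "malignant": (0.736, 0.03)}


def _truncated_normal(rng, mean, sd, lo=0.0, hi=1.0):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _random_rotation(rng) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, xq, yq, zq = q
    return np.array(
        [
            [1 - 2 * (yq**2 + zq**2), 2 * (xq * yq - zq * w), 2 * (xq * zq + yq * w)],
            [2 * (xq * yq + zq * w), 1 - 2 * (xq**2 + zq**2), 2 * (yq * zq - xq * w)],
            [2 * (xq * zq - yq * w), 2 * (yq * zq + xq * w), 1 - 2 * (xq**2 + yq**2)],
        ]
    )


def generate_cohort(
    n_benign: int,
    n_malignant: int,
    *,
    group_so2: dict | None = None,
    surrounding_so2: dict | None = None,
    size_range_mm: tuple = (8.0, 20.0),
    grid_shape: tuple = DEFAULT_GRID_SHAPE,
    voxel_size: tuple = DEFAULT_VOXEL_SIZE,
    extinction: ExtinctionTable | None = None,
    noise_sd: float = 0.05,
    energy_jitter_sd: float = 0.02,
    n_vessels: int = 3,
    vessel_radius_mm: float = 0.8,
    seed: int = 0,
):
    """Simulate a two-group cohort of tumour cases.

    Each case gets an independently drawn tumour (max diameter uniform over
    ``size_range_mm``, random orientation, SO2 from its group's truncated
    normal) plus peri-tumoral vessel capsules whose SO2 follows the group's
    surrounding distribution, forward-projected with noise and laser-energy
    jitter.  All randomness derives deterministically from ``seed`` via
    per-case spawned substreams, so a cohort is reproducible case by case.

    Returns
    -------
    (cases, truth) : (list of SyntheticCase, pandas.DataFrame)
        ``truth`` has one row per case with the generating parameters.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ConfigurationError("both group counts must be >= 1")
    group_so2 = dict(DEFAULT_GROUP_SO2, **(group_so2 or {}))
    surrounding_so2 = dict(DEFAULT_SURROUNDING_SO2, **(surrounding_so2 or {}))
    for g, (m, _) in group_so2.items():
        if not 0.0 < m < 1.0:
            raise ConfigurationError(f"group mean for {g!r} must lie in (0, 1)")
    extinction = extinction or ExtinctionTable.default()

    labels = ["benign"] * n_benign + ["malignant"] * n_malignant
    streams = np.random.SeedSequence(seed).spawn(len(labels))
    extents = (np.array(grid_shape) - 1) * np.array(voxel_size)

    cases, rows = [], []
    for i, (label, ss) in enumerate(zip(labels, streams)):
        rng = np.random.default_rng(ss)
        diameter = float(rng.uniform(*size_range_mm))
        a_major = diameter / 2.0
        axes = np.array([a_major, a_major * rng.uniform(0.6, 0.95), a_major * rng.uniform(0.6, 0.95)])
        R = _random_rotation(rng)
        # place so the 1.2x extension (plus vessel shell) stays inside the grid
        shell = 1.25
        half = np.sqrt(((R * (axes * shell)) ** 2).sum(axis=1)) + vessel_radius_mm
        lo, hi = half, extents - half
        if np.any(lo > hi):
            raise GeometryError(
                f"tumour of {diameter:.1f} mm (with extension) cannot fit in a "
                f"grid of extents {extents} mm"
            )
        center = lo + rng.uniform(size=3) * (hi - lo)
        tumour = Ellipsoid(center=center, semi_axes=axes, orientation=R)

        m_t, s_t = group_so2[label]
        m_s, s_s = surrounding_so2[label]
        t_so2 = _truncated_normal(rng, m_t, s_t)
        v_so2 = _truncated_normal(rng, m_s, s_s)

        vessels = []
        for _ in range(n_vessels):
            u0, u1 = rng.standard_normal(3), rng.standard_normal(3)
            u0 /= np.linalg.norm(u0)
            u1 /= np.linalg.norm(u1)
            s0, s1 = rng.uniform(1.02, 1.15, size=2)
            p0 = center + R @ (axes * s0 * u0)
            p1 = center + R @ (axes * s1 * u1)
            vessels.append(
                VesselSegment(
                    p0=tuple(p0), p1=tuple(p1), radius=vessel_radius_mm,
                    so2=v_so2, thb=150e-6,
                )
            )

        spec = PhantomSpec(
            grid_shape=tuple(grid_shape),
            voxel_size=tuple(voxel_size),
            tumour_ellipsoid=tumour,
            vessel_segments=tuple(vessels),
            tumour_so2=t_so2,
            tumour_thb=100e-6,
            background_thb=20e-6,
            background_so2=0.75,
            shell_so2=v_so2,
            shell_thb=40e-6,
            shell_factor=1.2,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        phantom = build_phantom(spec)
        fwd = ForwardModelConfig(
            energy_jitter_sd=energy_jitter_sd, seed=int(rng.integers(2**31))
        )
        volume = forward_project(phantom, extinction, fwd)
        case_id = f"case{i:03d}"
        cases.append(
            SyntheticCase(
                case_id=case_id,
                group=label,
                size_mm=diameter,
                volume=volume,
                contours=phantom.contour_stack,
                truth_tumour_so2=t_so2,
                truth_vessel_so2=v_so2,
                spec=spec,
            )
        )
        rows.append(
            {
                "case_id": case_id,
                "group": label,
                "size_mm": diameter,
                "truth_tumour_so2": t_so2,
                "truth_vessel_so2": v_so2,
            }
        )
    return cases, pd.DataFrame(rows)
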