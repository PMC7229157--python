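"""Two-wavelength spectral unmixing of photoacoustic volumes into oxygen saturation.

The photoacoustic amplitude at wavelength :math:`\\lambda` and position
:math:`r` is modelled as

.. math::

    PA(\\lambda, r) = \\Gamma\\, F(\\lambda, r)\\,
        \\bigl(C_{HbO_2}(r)\\,\\varepsilon_{HbO_2}(\\lambda)
             + C_{Hb}(r)\\,\\varepsilon_{Hb}(\\lambda)\\bigr)

with :math:`\\Gamma` the Grueneisen parameter, :math:`F` the local optical
fluence and :math:`\\varepsilon` the molar extinction coefficients.  When the
fluence is (approximately) equal at the two wavelengths — the operating
assumption for 750/830 nm imaging of breast tissue after laser-energy
normalization — the oxygen saturation

.. math::

    SO_2(r) = \\frac{C_{HbO_2}(r)}{C_{HbO_2}(r) + C_{Hb}(r)}

can be recovered per voxel from the ratio of the two amplitudes:

.. math::

    SO_2 = \\frac{PA_1\\,\\varepsilon_{Hb}(\\lambda_2)
                 - PA_2\\,\\varepsilon_{Hb}(\\lambda_1)}
                {PA_1\\,(\\varepsilon_{Hb}(\\lambda_2)
                        - \\varepsilon_{HbO_2}(\\lambda_2))
                 + PA_2\\,(\\varepsilon_{HbO_2}(\\lambda_1)
                         - \\varepsilon_{Hb}(\\lambda_1))}

Voxels whose estimate falls outside [0, 1] are handled by explicit policies
(negatives removed; slight over-unity clipped; gross over-unity removed) and
marked with NaN, never silently zeroed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

__all__ = [
    "ExtinctionTable",
    "DualWavelengthVolume",
    "SO2Volume",
    "normalize_by_energy",
    "compute_so2",
]

#: Default analysis wavelengths (nm): deoxy-Hb dominates absorption at the
#: first, oxy-Hb at the second.
DEFAULT_WAVELENGTHS = (750.0, 830.0)


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients of oxy-/deoxy-haemoglobin per wavelength.

    Parameters
    ----------
    wavelengths : tuple of float
        Wavelengths in nm.
    eps_hb_oxy, eps_hb_deoxy : tuple of float
        Extinction coefficients (cm^-1 M^-1) of oxy- and deoxy-haemoglobin,
        aligned with ``wavelengths``.
    version : str
        Identifier of the compilation the numbers came from.
    """

    wavelengths: tuple
    eps_hb_oxy: tuple
    eps_hb_deoxy: tuple
    version: str = "unversioned"

    def __post_init__(self):
        if not (len(self.wavelengths) == len(self.eps_hb_oxy) == len(self.eps_hb_deoxy)):
            raise ConfigurationError("extinction table columns must align")
        if min(self.eps_hb_oxy) <= 0 or min(self.eps_hb_deoxy) <= 0:
            raise ConfigurationError("extinction coefficients must be positive")
        # Spectral sanity: deoxy-Hb absorbs more strongly at 750 nm, oxy-Hb
        # at 830 nm.  Only checked when those wavelengths are present, since
        # the analysis wavelengths are configurable.
        for wl, oxy_stronger in ((750.0, False), (830.0, True)):
            if wl in self.wavelengths:
                oxy, de = self.coefficients(wl)
                if (oxy > de) != oxy_stronger:
                    raise ConfigurationError(
                        f"extinction table fails the spectral sanity check at {wl} nm"
                    )

    def coefficients(self, wavelength: float) -> tuple:
        """Return ``(eps_hb_oxy, eps_hb_deoxy)`` at *wavelength* (exact match)."""
        try:
            i = self.wavelengths.index(wavelength)
        except ValueError:
            raise ConfigurationError(
                f"wavelength {wavelength} nm not in extinction table "
                f"(has {self.wavelengths})"
            ) from None
        return self.eps_hb_oxy[i], self.eps_hb_deoxy[i]

    @classmethod
    def from_csv(cls, path, version: str | None = None) -> "ExtinctionTable":
        df = pd.read_csv(path, comment="#")
        return cls(
            wavelengths=tuple(float(w) for w in df["wavelength_nm"]),
            eps_hb_oxy=tuple(float(v) for v in df["eps_hb_oxy"]),
            eps_hb_deoxy=tuple(float(v) for v in df["eps_hb_deoxy"]),
            version=version or str(path),
        )

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """The compilation shipped with the package."""
        with resources.as_file(
            resources.files("paquant.data") / "hb_extinction.csv"
        ) as p:
            return cls.from_csv(p, version="paquant-builtin-1.0")


@dataclass
class DualWavelengthVolume:
    """Co-registered photoacoustic slice stacks at two wavelengths.

    ``stacks[wl]`` is a (slices, rows, cols) array of PA amplitudes in
    arbitrary (but common) units; ``frame_energies[wl]`` holds one recorded
    laser pulse energy per slice, in relative units.  The depth axis is the
    row axis (image top = skin); the slice axis is the probe sweep.
    """

    stacks: dict
    frame_energies: dict
    voxel_size: tuple  # (slice step, row, col) in mm
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        wls = self.wavelengths
        if len(wls) != 2:
            raise DataError(f"expected exactly two wavelengths, got {wls}")
        shapes = {self.stacks[w].shape for w in wls}
        if len(shapes) != 1:
            raise DataError(f"stacks differ in shape: {shapes}")
        shape = shapes.pop()
        if len(shape) != 3:
            raise DataError("stacks must be 3-D (slices, rows, cols)")
        for w in wls:
            e = np.asarray(self.frame_energies[w], dtype=float)
            if e.shape != (shape[0],):
                raise DataError(
                    f"frame energy count {e.shape} != slice count {shape[0]} at {w} nm"
                )
            if np.any(e <= 0):
                raise DataError(f"non-positive frame energy at {w} nm")
            self.frame_energies[w] = e
        if len(self.voxel_size) != 3 or min(self.voxel_size) <= 0:
            raise DataError("voxel_size must be three positive lengths (mm)")

    @property
    def wavelengths(self) -> tuple:
        return tuple(sorted(self.stacks))

    @property
    def shape(self) -> tuple:
        return self.stacks[self.wavelengths[0]].shape

    @property
    def normalized(self) -> bool:
        return bool(self.meta.get("energy_normalized", False))

    def copy(self) -> "DualWavelengthVolume":
        return DualWavelengthVolume(
            stacks={w: s.copy() for w, s in self.stacks.items()},
            frame_energies={w: e.copy() for w, e in self.frame_energies.items()},
            voxel_size=tuple(self.voxel_size),
            meta=copy.deepcopy(self.meta),
        )


@dataclass
class SO2Volume:
    """Per-voxel oxygen saturation on the source grid.

    Finite values lie in [0, 1]; voxels where no estimate exists (negative or
    grossly over-unity ratios, sub-floor signal, zero denominator) are NaN.
    """

    so2: np.ndarray
    voxel_size: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        finite = self.so2[np.isfinite(self.so2)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise DataError("finite SO2 values must lie in [0, 1]")

    @property
    def shape(self) -> tuple:
        return self.so2.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.so2)


def normalize_by_energy(
    volume: DualWavelengthVolume, nominal_energy: dict | None = None
) -> DualWavelengthVolume:
    """Divide each frame by its recorded laser energy relative to nominal.

    Frame *k* of the stack at wavelength *w* is divided by
    ``frame_energies[w][k] / nominal_energy[w]``; afterwards the recorded
    energies are all set to nominal, which makes the operation idempotent.
    When *nominal_energy* is omitted, energies are taken to be in relative
    units with nominal 1.0 at both wavelengths.  (Only the ratio of the two
    nominals matters for SO2: a common scale cancels in the unmixing ratio.)
    """
    out = volume.copy()
    for w in out.wavelengths:
        e = out.frame_energies[w]
        nominal = float(nominal_energy[w]) if nominal_energy else 1.0
        if nominal <= 0:
            raise DataError(f"nominal energy must be positive at {w} nm")
        out.stacks[w] = out.stacks[w] / (e / nominal)[:, None, None]
        out.frame_energies[w] = np.full_like(e, nominal)
    out.meta["energy_normalized"] = True
    return out


def compute_so2(
    volume: DualWavelengthVolume,
    extinction: ExtinctionTable,
    *,
    over_unity_delta: float = 0.05,
    floor_quantile: float = 0.01,
) -> SO2Volume:
    """Unmix a normalized dual-wavelength volume into per-voxel SO2.

    Parameters
    ----------
    volume : DualWavelengthVolume
        Must already be energy-normalized (see :func:`normalize_by_energy`).
    extinction : ExtinctionTable
        Must contain both of the volume's wavelengths.
    over_unity_delta : float
        Estimates in ``(1, 1 + delta]`` are clipped to 1 (noise symmetric to
        the removed negatives); estimates above ``1 + delta`` are invalid.
    floor_quantile : float
        Voxels whose amplitude at *both* wavelengths falls below this
        per-stack quantile are invalid — SO2 is only meaningful where there
        is haemoglobin signal, and the ratio of two near-zero amplitudes is
        noise.

    Returns
    -------
    SO2Volume
        NaN marks invalid voxels.  ``meta`` records the policies applied and
        the extinction-table version.
    """
    if not volume.normalized:
        raise DataError("volume must be energy-normalized before unmixing")
    wl1, wl2 = volume.wavelengths  # ascending: deoxy-dominant first by default
    eps_oxy_1, eps_de_1 = extinction.coefficients(wl1)
    eps_oxy_2, eps_de_2 = extinction.coefficients(wl2)

    pa1 = volume.stacks[wl1]
    pa2 = volume.stacks[wl2]

    num = pa1 * eps_de_2 - pa2 * eps_de_1
    den = pa1 * (eps_de_2 - eps_oxy_2) + pa2 * (eps_oxy_1 - eps_de_1)
    if eps_de_2 == eps_oxy_2 and eps_oxy_1 == eps_de_1:
        raise ConfigurationError(
            "degenerate extinction table: the two chromophores are "
            "spectrally identical at both wavelengths"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        so2 = num / den
    so2[~np.isfinite(so2)] = np.nan
    so2[np.abs(den) == 0] = np.nan

    # signal floor: both amplitudes in the bottom tail of their stack
    f1 = np.quantile(pa1, floor_quantile)
    f2 = np.quantile(pa2, floor_quantile)
    so2[(pa1 < f1) & (pa2 < f2)] = np.nan

    so2[so2 < 0] = np.nan                      # negatives removed
    over = so2 > 1
    clip = over & (so2 <= 1 + over_unity_delta)
    so2[clip] = 1.0                            # slight over-unity clipped
    so2[so2 > 1] = np.nan                      # gross over-unity removed

    meta = {
        "wavelengths_nm": (wl1, wl2),
        "extinction_version": extinction.version,
        "over_unity_delta": over_unity_delta,
        "floor_quantile": floor_quantile,
        "source_meta": dict(volume.meta),
    }
    return SO2Volume(so2=so2, voxel_size=tuple(volume.voxel_size), meta=meta)
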