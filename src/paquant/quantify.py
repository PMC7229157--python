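"""Regional SO2 biomarkers.

The biomarkers are thresholded volumetric means: the mean SO2 over a region's
voxels, keeping only finite values at or above a lower threshold (default
40%, below which estimates in breast tissue are treated as noise artefacts).
A separate strict-inequality window (40%, 100%) defines the vessel mask used
for 3-D network visualization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError
from .roi3d import Ellipsoid, VoxelMask, surrounding_mask
from .unmixing import SO2Volume

__all__ = [
    "RegionSummary",
    "QuantifyConfig",
    "volumetric_mean_so2",
    "vessel_mask",
    "summarize_case",
    "region_histogram",
]


@dataclass(frozen=True)
class RegionSummary:
    """Thresholded volumetric mean SO2 of one region of one case.

    ``volumetric_mean_so2`` is NaN and ``evaluable`` False when no voxel in
    the region carries a finite SO2 at or above the threshold.
    """

    label: str
    volumetric_mean_so2: float
    n_valid_voxels: int
    n_thresholded_out: int
    n_invalid: int
    n_voxels: int
    region_volume_mm3: float
    lower_threshold: float

    @property
    def evaluable(self) -> bool:
        return self.n_valid_voxels > 0


@dataclass(frozen=True)
class QuantifyConfig:
    lower_threshold: float = 0.40
    vessel_bounds: tuple = (0.40, 1.00)
    extension_factor: float = 1.2

    def __post_init__(self):
        if not 0.0 <= self.lower_threshold < 1.0:
            raise ConfigurationError("lower_threshold must lie in [0, 1)")
        lo, hi = self.vessel_bounds
        if not 0.0 <= lo < hi <= 1.0:
            raise ConfigurationError("vessel bounds must satisfy 0 <= lo < hi <= 1")


def volumetric_mean_so2(
    so2: SO2Volume,
    region: VoxelMask,
    lower_threshold: float = 0.40,
    label: str = "region",
) -> RegionSummary:
    """Mean SO2 over region voxels that are finite and >= lower_threshold.

    Voxels below the threshold are counted as thresholded-out, NaN voxels as
    invalid; an empty qualifying set yields an unevaluable summary (NaN mean),
    never a zero.
    """
    if not 0.0 <= lower_threshold < 1.0:
        raise ConfigurationError("lower_threshold must lie in [0, 1)")
    if not region.matches(so2.shape, so2.voxel_size):
        raise DataError(
            f"region geometry {region.data.shape}/{region.voxel_size} does not "
            f"match SO2 volume {so2.shape}/{so2.voxel_size}"
        )
    values = so2.so2[region.data]
    finite = np.isfinite(values)
    qualifying = finite & (values >= lower_threshold)
    n_valid = int(qualifying.sum())
    mean = float(values[qualifying].mean()) if n_valid else math.nan
    return RegionSummary(
        label=label,
        volumetric_mean_so2=mean,
        n_valid_voxels=n_valid,
        n_thresholded_out=int((finite & ~qualifying).sum()),
        n_invalid=int((~finite).sum()),
        n_voxels=int(values.size),
        region_volume_mm3=region.volume_mm3,
        lower_threshold=lower_threshold,
    )


def vessel_mask(so2: SO2Volume, lower: float = 0.40, upper: float = 1.00) -> VoxelMask:
    """Voxels with finite SO2 strictly between *lower* and *upper*.

    Strict inequalities on both ends: a voxel at exactly 40% or exactly 100%
    is excluded.  This is the pixel-selection rule for rendering the 3-D
    vessel network, intentionally distinct from the inclusive mean threshold.
    """
    if not 0.0 <= lower < upper <= 1.0:
        raise ConfigurationError("need 0 <= lower < upper <= 1")
    data = np.isfinite(so2.so2) & (so2.so2 > lower) & (so2.so2 < upper)
    return VoxelMask(data, tuple(so2.voxel_size))


def summarize_case(
    so2: SO2Volume,
    tumour_mask: VoxelMask,
    lve: Ellipsoid,
    extended: Ellipsoid,
    config: QuantifyConfig = QuantifyConfig(),
    *,
    contralateral_so2: SO2Volume | None = None,
    contralateral_tumour_mask: VoxelMask | None = None,
    case_id: str = "case",
) -> list:
    """Tumour and surrounding summaries for one case (plus contralateral ones
    when a second volume and mirrored masks are supplied).

    The peri-tumoral region is recomputed here from the extension ellipsoid
    and tumour mask, so the summaries are a pure function of the inputs.
    """
    try:
        surround = surrounding_mask(extended, tumour_mask)
        out = [
            volumetric_mean_so2(so2, tumour_mask, config.lower_threshold, "tumour"),
            volumetric_mean_so2(so2, surround, config.lower_threshold, "surrounding"),
        ]
        if contralateral_so2 is not None and contralateral_tumour_mask is not None:
            c_surround = surrounding_mask(extended, contralateral_tumour_mask)
            out.append(
                volumetric_mean_so2(
                    contralateral_so2, contralateral_tumour_mask,
                    config.lower_threshold, "contralateral_tumour",
                )
            )
            out.append(
                volumetric_mean_so2(
                    contralateral_so2, c_surround,
                    config.lower_threshold, "contralateral_surrounding",
                )
            )
        return out
    except (DataError, ConfigurationError) as exc:
        raise type(exc)(f"[{case_id}] {exc}") from exc


def region_histogram(
    so2: SO2Volume, region: VoxelMask, bins: int = 50, range_=(0.0, 1.0)
) -> pd.DataFrame:
    """Density histogram of finite SO2 values inside a region.

    Mirrors the per-region SO2 distribution plots as a plain table:
    columns ``bin_left, bin_right, density``.
    """
    values = so2.so2[region.data]
    values = values[np.isfinite(values)]
    counts, edges = np.histogram(values, bins=bins, range=range_, density=values.size > 0)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "density": counts}
    )
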