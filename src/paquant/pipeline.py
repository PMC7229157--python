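"""Per-case and cohort orchestration.

``analyze_case`` runs one volume through energy normalization, unmixing,
contour rasterization, ellipsoid fitting and regional quantification;
``run_cohort`` simulates a synthetic cohort and carries it through to the
group statistics (Mann-Whitney, Hodges-Lehmann, ROC).  Everything is a pure
function of the configuration and seed, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ConfigurationError, DataError, GeometryError, PaquantError
from .phantom import (
    DEFAULT_GRID_SHAPE,
    DEFAULT_VOXEL_SIZE,
    SyntheticCase,
    generate_cohort,
)
from .quantify import QuantifyConfig, summarize_case
from .roi3d import ContourStack, extend_ellipsoid, mvee, rasterize_contours
from .stats import SizeBin, enumerate_size_matched_subgroups, hodges_lehmann, roc_lower_is_positive
from .unmixing import DualWavelengthVolume, ExtinctionTable, compute_so2, normalize_by_energy

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "CaseResult", "CohortRunResult", "analyze_case", "run_cohort", "run"]


@dataclass
class RunConfig:
    """One flat configuration object driving simulation and analysis."""

    mode: str = "simulate+analyze"
    n_benign: int = 8
    n_malignant: int = 16
    grid_shape: tuple = DEFAULT_GRID_SHAPE
    voxel_size: tuple = DEFAULT_VOXEL_SIZE
    size_range_mm: tuple = (8.0, 20.0)
    group_so2: dict | None = None
    surrounding_so2: dict | None = None
    noise_sd: float = 0.05
    energy_jitter_sd: float = 0.02
    lower_threshold: float = 0.40
    vessel_bounds: tuple = (0.40, 1.00)
    over_unity_delta: float = 0.05
    extension_factor: float = 1.2
    mvee_tolerance: float = 1e-6
    cutoffs: tuple = (0.782, 0.779)
    max_depth_mm: float = 35.0
    subgroup_bins: tuple = ()
    extinction_path: str | None = None
    seed: int = 0
    out_dir: str | None = None
    write_volumes: bool = False

    def __post_init__(self):
        self.subgroup_bins = tuple(
            b if isinstance(b, SizeBin) else SizeBin(**b) for b in self.subgroup_bins
        )
        for name in ("lower_threshold", "over_unity_delta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.extension_factor < 1.0:
            raise ConfigurationError("extension_factor must be >= 1")
        if self.mode not in ("simulate", "analyze", "simulate+analyze"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.extinction_path and not Path(self.extinction_path).exists():
            raise ConfigurationError(f"extinction table {self.extinction_path} not found")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(str(path)).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        doc = dict(doc)
        for key in ("grid_shape", "voxel_size", "size_range_mm", "vessel_bounds", "cutoffs"):
            if key in doc:
                doc[key] = tuple(doc[key])
        if "subgroup_bins" in doc:
            doc["subgroup_bins"] = tuple(
                b if isinstance(b, SizeBin) else SizeBin(**b) for b in doc["subgroup_bins"]
            )
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subgroup_bins"] = [dataclasses.asdict(b) for b in self.subgroup_bins]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def extinction(self) -> ExtinctionTable:
        if self.extinction_path:
            return ExtinctionTable.from_csv(self.extinction_path)
        return ExtinctionTable.default()

    def quantify_config(self) -> QuantifyConfig:
        return QuantifyConfig(
            lower_threshold=self.lower_threshold,
            vessel_bounds=self.vessel_bounds,
            extension_factor=self.extension_factor,
        )


@dataclass
class CaseResult:
    case_id: str
    group: str
    size_mm: float
    summaries: list
    lve: object
    extended: object

    def row(self) -> dict:
        out = {"case_id": self.case_id, "group": self.group, "size_mm": self.size_mm}
        for s in self.summaries:
            out[f"{s.label}_mean_so2"] = s.volumetric_mean_so2
            out[f"{s.label}_n_valid"] = s.n_valid_voxels
        return out


@dataclass
class CohortRunResult:
    cohort: pd.DataFrame
    case_results: list
    comparisons: list
    rocs: dict
    truth: pd.DataFrame
    subgroups: pd.DataFrame | None = None
    skipped: list = field(default_factory=list)


def analyze_case(
    volume: DualWavelengthVolume,
    contours: ContourStack,
    config: RunConfig,
    *,
    case_id: str = "case",
    group: str = "",
    size_mm: float = float("nan"),
    extinction: ExtinctionTable | None = None,
) -> CaseResult:
    """Run one case from raw dual-wavelength stacks to region summaries."""
    extinction = extinction or config.extinction()
    vol = normalize_by_energy(volume)
    so2 = compute_so2(
        vol, extinction, over_unity_delta=config.over_unity_delta
    )
    tumour_mask = rasterize_contours(contours, vol.shape, vol.voxel_size)

    # eligibility: the distal tumour margin must be within imaging depth
    rows = np.nonzero(tumour_mask.data.any(axis=(0, 2)))[0]
    if rows.size:
        distal_mm = rows.max() * vol.voxel_size[1]
        if distal_mm > config.max_depth_mm:
            raise GeometryError(
                f"[{case_id}] tumour distal margin at {distal_mm:.1f} mm exceeds "
                f"the {config.max_depth_mm:.1f} mm imaging depth"
            )

    lve = mvee(contours.points3d(), tolerance=config.mvee_tolerance)
    extended = extend_ellipsoid(lve, config.extension_factor)
    summaries = summarize_case(
        so2, tumour_mask, lve, extended, config.quantify_config(), case_id=case_id
    )
    return CaseResult(
        case_id=case_id, group=group, size_mm=size_mm,
        summaries=summaries, lve=lve, extended=extended,
    )


def _compare(cohort: pd.DataFrame, column: str, cutoffs) -> tuple:
    mal = cohort.loc[cohort["group"] == "malignant", column].dropna()
    ben = cohort.loc[cohort["group"] == "benign", column].dropna()
    comparison = hodges_lehmann(mal, ben, groups=("malignant", "benign"))
    scores = pd.concat([mal, ben])
    labels = np.array([True] * len(mal) + [False] * len(ben))
    roc = roc_lower_is_positive(scores.to_numpy(), labels, cutoffs=cutoffs)
    return comparison, roc


def run_cohort(config: RunConfig) -> CohortRunResult:
    """Simulate a cohort and push every case through the full pipeline."""
    extinction = config.extinction()
    cases, truth = generate_cohort(
        config.n_benign,
        config.n_malignant,
        group_so2=config.group_so2,
        surrounding_so2=config.surrounding_so2,
        size_range_mm=config.size_range_mm,
        grid_shape=config.grid_shape,
        voxel_size=config.voxel_size,
        extinction=extinction,
        noise_sd=config.noise_sd,
        energy_jitter_sd=config.energy_jitter_sd,
        seed=config.seed,
    )
    case_results, skipped = [], []
    for case in cases:
        try:
            case_results.append(
                analyze_case(
                    case.volume, case.contours, config,
                    case_id=case.case_id, group=case.group, size_mm=case.size_mm,
                    extinction=extinction,
                )
            )
        except PaquantError as exc:
            logger.warning("case %s skipped: %s", case.case_id, exc)
            skipped.append((case.case_id, str(exc)))
    if not case_results:
        raise DataError("all cases failed analysis")

    cohort = pd.DataFrame([c.row() for c in case_results])
    comparisons, rocs = [], {}
    for column, label in (
        ("tumour_mean_so2", "tumour"),
        ("surrounding_mean_so2", "surrounding"),
    ):
        comparison, roc = _compare(cohort, column, config.cutoffs)
        comparisons.append((label, comparison))
        rocs[label] = roc

    subgroups = None
    if config.subgroup_bins:
        subgroups = subgroup_analysis(cohort, config.subgroup_bins, config.cutoffs)
    return CohortRunResult(
        cohort=cohort, case_results=case_results, comparisons=comparisons,
        rocs=rocs, truth=truth, subgroups=subgroups, skipped=skipped,
    )


def subgroup_analysis(cohort: pd.DataFrame, bins, cutoffs=()) -> pd.DataFrame:
    """One comparison row per size-matched subgroup (tumour-region SO2)."""
    rows = []
    for ids in enumerate_size_matched_subgroups(cohort, bins):
        sub = cohort[cohort["case_id"].isin(ids)]
        comparison, roc = _compare(sub, "tumour_mean_so2", cutoffs)
        row = {
            "subgroup": "|".join(ids),
            "n_malignant": int((sub["group"] == "malignant").sum()),
            "n_benign": int((sub["group"] == "benign").sum()),
            "p_value": comparison.p_value,
            "hl_estimate": comparison.estimate,
            "ci_low": comparison.ci_low,
            "ci_high": comparison.ci_high,
            "auc": roc.auc,
        }
        for c, (sens, spec) in roc.cutoff_metrics.items():
            row[f"sens_at_{c:g}"] = sens
            row[f"spec_at_{c:g}"] = spec
        rows.append(row)
    return pd.DataFrame(rows)


def _write_outputs(result: CohortRunResult, config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.cohort.to_csv(out_dir / "cohort.csv", index=False)
    result.truth.to_csv(out_dir / "truth.csv", index=False)
    comp_rows = []
    for label, c in result.comparisons:
        comp_rows.append(
            {
                "region": label,
                "groups": "-".join(c.groups),
                "n": f"{c.n[0]}v{c.n[1]}",
                "u_statistic": c.u_statistic,
                "p_value": c.p_value,
                "hl_estimate_pp": 100 * c.estimate,
                "ci_low_pp": 100 * c.ci_low,
                "ci_high_pp": 100 * c.ci_high,
                "auc": result.rocs[label].auc,
            }
        )
    pd.DataFrame(comp_rows).to_csv(out_dir / "comparisons.csv", index=False)
    for label, roc in result.rocs.items():
        pd.DataFrame(
            {
                "threshold": roc.thresholds,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
            }
        ).to_csv(out_dir / f"roc_{label}.csv", index=False)
    if result.subgroups is not None:
        result.subgroups.to_csv(out_dir / "subgroups.csv", index=False)
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_cases": len(result.case_results),
        "n_skipped": len(result.skipped),
        "skipped": result.skipped,
        "config": config.to_dict(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run(config: RunConfig) -> CohortRunResult:
    """Execute a full simulate+analyze run, writing artifacts if configured."""
    result = run_cohort(config)
    if config.out_dir:
        _write_outputs(result, config, Path(config.out_dir))
    return result
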