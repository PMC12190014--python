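"""Orchestration and file I/O tying the analysis stages together.

Two workflows are exposed:

* :func:`run_quantify` — single-timepoint quantification: per-subject
  NIfTI activity volumes and tumor masks plus a metadata table in, a
  tidy per-subject table of core/margin %ID/ml, core-to-margin ratio and
  spatial-pattern call out.
* :func:`run_adaptive_study` — the PET-guided adaptation workflow: a
  cohort table with day-5 ratios and growth outcomes in, per-arm and
  pooled response accounting out.

File conventions: volumes and masks are NIfTI-1 on identical grids (a
grid mismatch is an error, never a silent resample); tables are CSV;
reports are additionally emitted as JSON. Every output row carries the
config hash and seed used, so re-runs on identical inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import decision, histology, spatial
from .errors import AlignmentError, ConfigurationError
from .radiometrics import ActivityVolume, InjectionContext
from .spatial import RegionMask

log = logging.getLogger("cd4pet")

METADATA_COLUMNS = ("subject_id", "injected_activity_Bq", "injection_time", "scan_time")
GAMMA_COLUMNS = (
    "organ_label", "net_cpm", "count_time", "mass_g", "standard_cpm",
    "standard_fraction",
)


@dataclass
class StudyConfig:
    """Flat configuration for a study run (YAML-loadable).

    Paths are resolved relative to the config file's directory when
    loaded with :meth:`from_yaml`.
    """

    volumes_dir: Optional[str] = None
    masks_dir: Optional[str] = None
    organ_masks_dir: Optional[str] = None  # files named <subject>__<organ>.nii
    metadata: Optional[str] = None
    cohort: Optional[str] = None
    growth: Optional[str] = None
    output_dir: str = "cd4pet_out"
    analysis_mode: str = "slice2d"
    core_scale: float = 0.5
    threshold: float = decision.STRATIFICATION_THRESHOLD
    u_min: float = 0.3  # pattern floor; override with the WT-group median
    r_hi: float = decision.STRATIFICATION_THRESHOLD
    r_lo: float = 1.0 / decision.STRATIFICATION_THRESHOLD
    margin_width_um: float = histology.MARGIN_WIDTH_UM
    hpf_area_mm2: float = histology.HPF_AREA_MM2
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.core_scale < 1):
            raise ConfigurationError(
                f"core_scale must be in (0, 1), got {self.core_scale}"
            )
        if self.analysis_mode not in ("slice2d", "volume3d"):
            raise ConfigurationError(
                f"analysis_mode must be slice2d or volume3d, got "
                f"{self.analysis_mode!r}"
            )
        if self.r_lo > self.r_hi:
            raise ConfigurationError("r_lo must not exceed r_hi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("volumes_dir", "masks_dir", "organ_masks_dir", "metadata",
                    "cohort", "growth", "output_dir"):
            val = getattr(cfg, key)
            if val is not None and not Path(val).is_absolute():
                setattr(cfg, key, str(path.parent / val))
        return cfg

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_volume(path: str | Path, scan_time: float = 0.0) -> ActivityVolume:
    """Read a NIfTI activity volume (Bq/ml); spacing from header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return ActivityVolume(voxels=data, spacing=spacing, scan_time=scan_time)


def load_mask(path: str | Path, label: str = "tumor") -> RegionMask:
    """Read a NIfTI 0/1 mask as a RegionMask."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return RegionMask(grid=data > 0.5, label=label, spacing=spacing)


def save_volume(
    path: str | Path, data: np.ndarray, spacing: tuple[float, ...]
) -> None:
    """Write an array as NIfTI-1 with a diagonal affine from the spacing."""
    affine = np.diag(list(spacing) + [1.0] * (4 - len(spacing)))
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def _find_subject_file(directory: Path, subject_id: str) -> Path:
    for suffix in (".nii.gz", ".nii"):
        candidate = directory / f"{subject_id}{suffix}"
        if candidate.exists():
            return candidate
    raise FileNotFoundError(f"no NIfTI file for {subject_id!r} in {directory}")


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Per-subject metadata CSV; validates the required columns."""
    df = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"metadata table lacks columns {sorted(missing)}")
    return df


def load_gamma_records(path: str | Path) -> list["GammaRecord"]:
    """Gamma-counter CSV (organ_label, net_cpm, count_time, mass_g,
    standard_cpm, standard_fraction) as GammaRecord objects."""
    from .radiometrics import GammaRecord

    df = pd.read_csv(path)
    missing = set(GAMMA_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"gamma table lacks columns {sorted(missing)}")
    return [
        GammaRecord(
            organ_label=str(r.organ_label),
            net_counts=float(r.net_cpm),
            count_time=float(r.count_time),
            mass=float(r.mass_g),
            standard_counts=float(r.standard_cpm),
            standard_fraction=float(r.standard_fraction),
        )
        for r in df.itertuples(index=False)
    ]


def load_cells(path: str | Path) -> list[histology.CellRecord]:
    """Cell-centroid CSV: x_um, y_um, plus one 0/1 column per marker."""
    df = pd.read_csv(path)
    for col in ("x_um", "y_um"):
        if col not in df.columns:
            raise ConfigurationError(f"cell table lacks column {col!r}")
    marker_cols = [c for c in df.columns if c not in ("x_um", "y_um")]
    cells = []
    for row in df.itertuples(index=False):
        markers = frozenset(
            c for c in marker_cols if int(getattr(row, c)) == 1
        )
        cells.append(
            histology.CellRecord(x=float(row.x_um), y=float(row.y_um),
                                 phenotype=markers)
        )
    return cells


def run_quantify(config: StudyConfig) -> pd.DataFrame:
    """Per-subject core/margin quantification and pattern classification.

    For every row of the metadata table, loads the subject's activity
    volume and tumor mask (same grid required), derives the core and
    margin, computes decay-corrected region means in %ID/ml, the
    core-to-margin ratio, and the spatial-pattern call. Writes
    ``quantify_scores.csv`` plus a JSON report under ``output_dir`` and
    returns the table.
    """
    if not (config.volumes_dir and config.masks_dir and config.metadata):
        raise ConfigurationError(
            "run_quantify needs volumes_dir, masks_dir and metadata"
        )
    log.info("quantify: reading metadata from %s", config.metadata)
    meta = load_metadata(config.metadata)
    thresholds = {"u_min": config.u_min, "r_hi": config.r_hi, "r_lo": config.r_lo}
    rows = []
    organ_rows = []
    for rec in meta.itertuples(index=False):
        sid = str(rec.subject_id)
        vol_path = _find_subject_file(Path(config.volumes_dir), sid)
        mask_path = _find_subject_file(Path(config.masks_dir), sid)
        volume = load_volume(vol_path, scan_time=float(rec.scan_time))
        tumor = load_mask(mask_path)
        if volume.voxels.shape != tumor.grid.shape:
            raise AlignmentError(
                f"grid mismatch for subject {sid}: volume {vol_path.name} is "
                f"{volume.voxels.shape}, mask {mask_path.name} is "
                f"{tumor.grid.shape}"
            )
        ctx = InjectionContext(
            injected_activity=float(rec.injected_activity_Bq),
            injection_time=float(rec.injection_time),
        )
        core, margin = spatial.derive_core_margin(
            tumor, scale=config.core_scale, mode=config.analysis_mode
        )
        core_mean = spatial.region_mean_uptake(volume, core, ctx)
        margin_mean = (
            spatial.region_mean_uptake(volume, margin, ctx) if margin else 0.0
        )
        tumor_mean = spatial.region_mean_uptake(volume, tumor, ctx)
        score = spatial.core_margin_ratio(
            core_mean, margin_mean, config.analysis_mode,
            getattr(core, "slice_index", None),
        )
        call = decision.classify_pattern(core_mean, margin_mean, thresholds)
        log.debug("quantify: %s ratio=%.3f call=%s", sid, score.ratio, call.call)
        rows.append(
            {
                "subject_id": sid,
                "tumor_mean_pid_ml": tumor_mean,
                "core_mean_pid_ml": core_mean,
                "margin_mean_pid_ml": margin_mean,
                "core_margin_ratio": score.ratio,
                "undefined_ratio": score.undefined_ratio,
                "slice_index": score.slice_index,
                "pattern": call.call,
                "config_hash": config.config_hash,
                "seed": config.seed,
            }
        )
        if config.organ_masks_dir:
            for organ_path in sorted(Path(config.organ_masks_dir).glob(
                    f"{sid}__*.nii*")):
                organ = organ_path.name.split("__", 1)[1].split(".nii")[0]
                organ_mask = load_mask(organ_path, label=organ)
                if organ_mask.grid.shape != volume.voxels.shape:
                    raise AlignmentError(
                        f"grid mismatch for subject {sid}: organ mask "
                        f"{organ_path.name} is {organ_mask.grid.shape}, "
                        f"volume is {volume.voxels.shape}"
                    )
                organ_rows.append(
                    {
                        "subject_id": sid,
                        "organ": organ,
                        "mean_pid_ml": spatial.region_mean_uptake(
                            volume, organ_mask, ctx
                        ),
                        "config_hash": config.config_hash,
                        "seed": config.seed,
                    }
                )
    table = pd.DataFrame(rows)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "quantify_scores.csv", index=False)
    if organ_rows:
        pd.DataFrame(organ_rows).to_csv(out / "organ_uptake.csv", index=False)
    (out / "quantify_report.json").write_text(
        json.dumps(
            {
                "n_subjects": len(table),
                "patterns": table["pattern"].value_counts().to_dict(),
                "config_hash": config.config_hash,
                "seed": config.seed,
            },
            indent=2,
        )
    )
    log.info("quantify: wrote %d subjects to %s", len(table), out)
    return table


def run_adaptive_study(
    config: StudyConfig, cohort: Optional[pd.DataFrame] = None
) -> decision.WorkflowSummary:
    """PET-guided adaptive workflow accounting.

    The cohort table (given directly or read from ``config.cohort``)
    needs ``subject_id``, a day-5 ``ratio``, and either a ``responder``
    boolean or ``volume_d0``/``volume_d7`` columns from which the growth
    rule derives it. Stratifies every subject by the threshold rule,
    tabulates per-arm and pooled response rates, writes
    ``adaptive_report.json`` and ``adaptive_cohort.csv``, and returns
    the summary. When a follow-up ``ratio_d12`` column is present, a
    ratio-change table is included in the report.
    """
    if cohort is None:
        if not config.cohort:
            raise ConfigurationError("run_adaptive_study needs a cohort table")
        cohort = pd.read_csv(config.cohort)
    cohort = cohort.copy()
    if "responder" not in cohort.columns:
        if not {"volume_d0", "volume_d7"} <= set(cohort.columns):
            raise ConfigurationError(
                "cohort needs a responder column or volume_d0/volume_d7"
            )
        cohort["responder"] = [
            decision.growth_responder({0: v0, 7: v7})
            for v0, v7 in zip(cohort["volume_d0"], cohort["volume_d7"])
        ]
    log.info("adaptive: stratifying %d subjects at ratio > %.2f",
             len(cohort), config.threshold)
    summary = decision.adaptive_workflow(cohort, threshold=config.threshold)
    cohort["arm"] = [
        "continue_mono" if r > config.threshold else "add_combo"
        for r in cohort["ratio"]
    ]
    cohort["config_hash"] = config.config_hash
    cohort["seed"] = config.seed
    report = {
        "workflow": summary.to_dict(),
        "threshold": config.threshold,
        "config_hash": config.config_hash,
        "seed": config.seed,
    }
    if "ratio_d12" in cohort.columns:
        followup = cohort[["subject_id", "arm", "ratio", "ratio_d12"]].copy()
        followup["ratio_change"] = followup["ratio_d12"] - followup["ratio"]
        report["followup_ratio_change"] = followup.to_dict(orient="records")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "adaptive_cohort.csv", index=False)
    (out / "adaptive_report.json").write_text(json.dumps(report, indent=2))
    log.info(
        "adaptive: pooled %d/%d responders (%d%%), continue_mono %d%%",
        summary.pooled.responders, summary.pooled.total, summary.pooled.rate,
        summary.continue_mono_percent,
    )
    return summary


def run_histo(
    cells: list[histology.CellRecord],
    core_mask: RegionMask,
    config: StudyConfig,
) -> dict:
    """Histology quantification: regions, densities, ratio, QC, Tregs."""
    regions = histology.build_tissue_regions(
        core_mask, margin_width=config.margin_width_um
    )
    counts = histology.assign_cells(cells, regions)
    score = histology.density_core_margin_score(counts["core"], counts["margin"])
    result = {"config_hash": config.config_hash, "seed": config.seed}
    for region in ("core", "margin"):
        rc = counts[region]
        proxy = histology.cd4_proxy_counts(rc)
        dens = histology.region_density(rc)
        cd4 = rc.total("CD3+CD8-")
        tregs = rc.total("CD4+FoxP3+")
        result[region] = {
            "area_mm2": rc.area,
            "cd4_proxy_count": proxy.cd4_proxy_count,
            "dn_fraction": proxy.dn_fraction,
            "qc": proxy.qc,
            "cd4_per_mm2": dens["cells_per_mm2"],
            "treg_fraction": (
                histology.treg_fraction(tregs, cd4) if cd4 else None
            ),
        }
    result["core_margin_ratio"] = score.ratio
    result["pattern"] = decision.classify_pattern(
        result["core"]["cd4_per_mm2"],
        result["margin"]["cd4_per_mm2"],
        # density floor: scale u_min to the density scale is study-specific,
        # so the density pattern call reuses the ratio thresholds with a
        # zero floor unless configured otherwise
        {"u_min": 0.0, "r_hi": config.r_hi, "r_lo": config.r_lo},
    ).call
    return result
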