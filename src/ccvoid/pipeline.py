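"""Study-level orchestration: manifest in, Tables-1/2-shaped summaries out.

Per record: build the exclusion mask (large superficial vessels + FAZ), run
the 1-SD flow-void quantification on the choriocapillaris slab, compute the
three retinal perfusion densities, and measure subfoveal thicknesses from
the structural B-scan. Records are aggregated to mean ± SD per
(visit, timepoint) and each variable is tested for diurnal variation with a
repeated-measures ANOVA per visit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import dataio
from .dataio import (METRIC_COLUMNS, ResultsTable, StudyManifest,
                     filter_by_quality, read_angiogram, read_boundaries,
                     read_manifest)
from .errors import CCVoidError, UsageError
from .flowvoid import analyze_cc
from .masking import (MaskingConfig, empty_mask, exclusion_mask,
                      large_vessel_mask, rasterize_faz)
from .perfusion import FrangiConfig, binarize_global, frangi_enhance, perfusion_density
from .stats import LongitudinalMatrix, RMAnovaResult, rm_anova
from .thickness import BScan, measure_thickness

logger = logging.getLogger(__name__)

REQUIRED_SLABS = ("CC", "SVP", "DVP", "BSCAN")


@dataclass
class RunConfig:
    """All knobs of a study run, serializable to/from a plain dict (YAML)."""

    lateral_scale_um: float = 10.0
    axial_scale_um: float = 1.95
    connectivity: int = 8
    min_void_px: int = 0
    frangi: FrangiConfig = field(default_factory=FrangiConfig)
    masking: MaskingConfig = field(default_factory=MaskingConfig)
    min_signal_strength: float = 8.0
    gg_policy: str = "conditional"
    icc_model: str = "icc2_1"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "frangi" in d and isinstance(d["frangi"], dict):
            d["frangi"] = FrangiConfig(**d["frangi"])
        if "masking" in d and isinstance(d["masking"], dict):
            d["masking"] = MaskingConfig(**d["masking"])
        return cls(**d)


@dataclass
class StudyResult:
    records: ResultsTable
    summary: pd.DataFrame
    anova: dict  # variable -> visit -> RMAnovaResult


def _sidecar(path: Path, suffix: str) -> Path:
    return path.with_name(path.stem + suffix)


def _quantify_record(paths: dict, config: RunConfig) -> dict:
    svp = read_angiogram(paths["SVP"], "SVP", config.lateral_scale_um)
    dvp = read_angiogram(paths["DVP"], "DVP", config.lateral_scale_um)
    cc = read_angiogram(paths["CC"], "CC", config.lateral_scale_um)

    large = large_vessel_mask(svp, config.masking)
    faz_path = _sidecar(paths["SVP"], "_faz.json")
    if faz_path.exists():
        faz = rasterize_faz(dataio.read_polygon(faz_path), svp.shape)
    else:
        logger.warning("no FAZ polygon beside %s; FAZ exclusion empty", paths["SVP"])
        faz = empty_mask(svp.shape, "faz")
    excl = exclusion_mask(large, faz)

    fv, _ = analyze_cc(cc, excl, connectivity=config.connectivity,
                       min_void_px=config.min_void_px)

    sup = perfusion_density(binarize_global(frangi_enhance(svp, config.frangi)))
    deep = perfusion_density(binarize_global(frangi_enhance(dvp, config.frangi)))
    lv_pct = perfusion_density(large)

    arr = iio.imread(paths["BSCAN"])
    boundaries = read_boundaries(_sidecar(paths["BSCAN"], "_boundaries.csv"))
    bscan = BScan(arr / 255.0, config.axial_scale_um, boundaries=boundaries)
    th = measure_thickness(bscan)

    logger.info(
        "record quantified: threshold=%.5f analyzed_um2=%.0f excl_frac=%.3f "
        "voids=%d density=%.2f", fv.threshold_used, fv.analyzed_area_um2,
        excl.pixels.mean(), fv.count, fv.density_pct)
    return {
        "void_density_pct": fv.density_pct,
        "void_mean_size_um2": fv.mean_size_um2,
        "void_count": fv.count,
        "large_vessel_density_pct": lv_pct,
        "superficial_density_pct": sup,
        "deep_density_pct": deep,
        "retinal_thickness_um": th.retinal_um,
        "choroidal_thickness_um": th.choroidal_um,
    }


def _select_eye(group: pd.DataFrame) -> str:
    """Right eye preferred; fall back to the left."""
    eyes = sorted(group["eye"].unique())
    return "OD" if "OD" in eyes else eyes[0]


def run_study(manifest: Union[StudyManifest, str, Path],
              config: Optional[RunConfig] = None,
              out_dir=None) -> StudyResult:
    """Quantify every record of a manifest and summarize diurnal variation.

    Applies the quality filter, quantifies each (subject, visit, timepoint)
    record with all four slabs present (records with missing slabs are
    skipped with a logged reason), aggregates mean ± SD per (visit,
    timepoint), and runs a repeated-measures ANOVA per variable per visit.
    Deterministic given inputs and config; when ``out_dir`` is set, writes
    ``records.csv``, ``summary.csv`` and ``anova.json`` there.
    """
    if not isinstance(manifest, StudyManifest):
        manifest = read_manifest(manifest)
    config = config or RunConfig()

    filtered = filter_by_quality(manifest, config.min_signal_strength)
    if len(filtered) == 0:
        raise CCVoidError("no records left after the quality filter")

    df = filtered.records
    rows = []
    for sid, subj_group in df.groupby("subject_id", sort=True):
        eye = _select_eye(subj_group)
        eye_group = subj_group[subj_group["eye"] == eye]
        for (visit, tp), rec in eye_group.groupby(["visit", "timepoint"], sort=True):
            slabs = dict(zip(rec["slab"], rec["path"]))
            missing = [s for s in REQUIRED_SLABS if s not in slabs]
            if missing:
                logger.warning("skipping %s v%s %s: missing slabs %s",
                               sid, visit, tp, missing)
                continue
            paths = {s: filtered.resolve(slabs[s]) for s in REQUIRED_SLABS}
            metrics = _quantify_record(paths, config)
            rows.append({"subject_id": sid, "eye": eye, "visit": visit,
                         "timepoint": tp, **metrics})

    if not rows:
        raise CCVoidError("no quantifiable records in the manifest")
    records = ResultsTable(pd.DataFrame(rows))

    summary = (records.rows
               .groupby(["visit", "timepoint"], sort=True)[METRIC_COLUMNS]
               .agg(["mean", "std"]))
    summary.columns = [f"{var}_{stat}" for var, stat in summary.columns]
    summary = summary.reset_index()

    anova: dict = {}
    for var in METRIC_COLUMNS:
        anova[var] = {}
        for visit, vgroup in records.rows.groupby("visit", sort=True):
            try:
                mat = LongitudinalMatrix.from_long(vgroup, value=var)
                anova[var][int(visit)] = rm_anova(mat, policy=config.gg_policy)
            except UsageError as exc:
                logger.warning("ANOVA skipped for %s visit %s: %s", var, visit, exc)

    result = StudyResult(records=records, summary=summary, anova=anova)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: StudyResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    dataio.write_results(result.records, out / "records.csv")
    result.summary.to_csv(out / "summary.csv", index=False, float_format="%.6f")
    payload = {
        var: {str(visit): _jsonable(dataclasses.asdict(res))
              for visit, res in per_visit.items()}
        for var, per_visit in result.anova.items()
    }
    (out / "anova.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(d: dict) -> dict:
    out = {}
    for key, val in d.items():
        if isinstance(val, (np.floating, np.integer)):
            val = val.item()
        if isinstance(val, float) and not np.isfinite(val):
            val = None if np.isnan(val) else ("inf" if val > 0 else "-inf")
        out[key] = val
    return out
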