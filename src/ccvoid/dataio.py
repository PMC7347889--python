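"""Reading and writing of angiograms, masks, polygons, manifests and results.

Conventions used throughout the package: images are row-major with the origin
at the top-left corner and 0-based indices; polygon vertices are stored in
(column, row) order; intensities are held as floats on [0, 1] in memory and
quantized to 8 bits only at the I/O boundary, so threshold arithmetic is
independent of bit depth.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: slab identifiers: superficial plexus, deep plexus, choriocapillaris,
#: plus the structural B-scan pseudo-slab used in study manifests.
SLABS = ("SVP", "DVP", "CC")

MANIFEST_COLUMNS = [
    "subject_id", "eye", "visit", "timepoint", "slab", "path", "signal_strength",
]

#: fixed column order of per-record results tables (the Tables 1–2 variable set).
METRIC_COLUMNS = [
    "void_density_pct", "void_mean_size_um2", "void_count",
    "large_vessel_density_pct", "superficial_density_pct", "deep_density_pct",
    "retinal_thickness_um", "choroidal_thickness_um",
]
RESULT_COLUMNS = ["subject_id", "eye", "visit", "timepoint", *METRIC_COLUMNS]

_PCT_COLUMNS = [
    "void_density_pct", "large_vessel_density_pct",
    "superficial_density_pct", "deep_density_pct",
]
_NONNEG_COLUMNS = [
    "void_mean_size_um2", "void_count", "retinal_thickness_um",
    "choroidal_thickness_um",
]


@dataclass
class EnfaceAngiogram:
    """A 2-D en-face OCTA intensity grid with slab label and lateral scale.

    ``pixels`` holds unit-interval floats; ``lateral_scale_um`` is the edge
    length of one pixel in micrometers (10 µm/px for a 300-px, 3-mm field).
    """

    pixels: np.ndarray
    slab: str
    lateral_scale_um: float
    subject_id: Optional[str] = None
    visit: Optional[int] = None
    timepoint: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise FormatError("angiogram pixels must be a 2-D grid")
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise FormatError("angiogram grid must be square")
        if self.slab not in SLABS:
            raise ValidationError(f"unknown slab {self.slab!r}; expected one of {SLABS}")
        if not self.lateral_scale_um > 0:
            raise ValidationError("lateral_scale_um must be positive")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValidationError("intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def read_angiogram(
    path, slab: str, lateral_scale_um: float, **metadata
) -> EnfaceAngiogram:
    """Load a single-channel 8-bit raster (TIFF/PNG) as an angiogram.

    Pixel values are rescaled to [0, 1] on load. Multi-channel or non-8-bit
    files raise :class:`FormatError`.
    """
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected single-channel image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit image, got dtype {arr.dtype}")
    return EnfaceAngiogram(arr / 255.0, slab, lateral_scale_um, **metadata)


def write_angiogram(img: EnfaceAngiogram, path) -> None:
    """Write an angiogram as an 8-bit grayscale TIFF or PNG (by suffix)."""
    write_image(img.pixels, path)


def write_image(pixels: np.ndarray, path) -> None:
    """Quantize a unit-interval float image to uint8 and write it."""
    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255.0).astype(np.uint8))


# ---------------------------------------------------------------------------
# polygons


def write_polygon(vertices: Sequence, path) -> None:
    """Persist a polygon as JSON ``{"vertices": [[c, r], ...]}``."""
    verts = [[float(c), float(r)] for c, r in vertices]
    Path(path).write_text(json.dumps({"vertices": verts}))


def read_polygon(path) -> list:
    data = json.loads(Path(path).read_text())
    if "vertices" not in data:
        raise FormatError(f"{path}: polygon JSON lacks 'vertices'")
    return [(float(c), float(r)) for c, r in data["vertices"]]


# ---------------------------------------------------------------------------
# study manifests


@dataclass
class StudyManifest:
    """One row per scan: subject, eye, visit, timepoint, slab, path, quality.

    ``base_dir`` anchors relative paths (set when read from disk), so
    manifests stay portable across machines.
    """

    records: pd.DataFrame
    base_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=MANIFEST_COLUMNS).copy()
        df["signal_strength"] = df["signal_strength"].astype(float)
        if ((df["signal_strength"] < 0) | (df["signal_strength"] > 10)).any():
            raise ValidationError("signal_strength must lie in [0, 10]")
        key = ["subject_id", "eye", "visit", "timepoint", "slab"]
        if df.duplicated(subset=key).any():
            raise ValidationError("manifest records must be unique per " + str(key))
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def resolve(self, path) -> Path:
        p = Path(path)
        if not p.is_absolute() and self.base_dir is not None:
            p = self.base_dir / p
        return p


def read_manifest(path) -> StudyManifest:
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "eye": str, "timepoint": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    return StudyManifest(df[MANIFEST_COLUMNS], base_dir=path.parent)


def write_manifest(manifest: StudyManifest, path) -> None:
    manifest.records.to_csv(Path(path), index=False)


def filter_by_quality(manifest: StudyManifest, min_strength: float = 8.0) -> StudyManifest:
    """Keep only records with ``signal_strength >= min_strength``.

    Mirrors the acquisition rule that only scans with a signal-strength score
    of 8 or above enter the analysis. Idempotent and order-preserving.
    """
    keep = manifest.records["signal_strength"] >= min_strength
    excluded = int((~keep).sum())
    if excluded:
        logger.info("filter_by_quality: excluded %d of %d records (min_strength=%s)",
                    excluded, len(manifest), min_strength)
    out = StudyManifest(manifest.records[keep], base_dir=manifest.base_dir)
    if len(out) == 0:
        warnings.warn("filter_by_quality: no records meet the quality threshold")
    return out


# ---------------------------------------------------------------------------
# results tables


@dataclass
class ResultsTable:
    """Per-(subject, visit, timepoint) quantification results.

    Columns follow :data:`RESULT_COLUMNS`; percentages must lie in [0, 100]
    and sizes/thicknesses must be non-negative.
    """

    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RESULT_COLUMNS))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows, columns=RESULT_COLUMNS).copy()
        for col in _PCT_COLUMNS:
            vals = df[col].astype(float)
            if ((vals < 0) | (vals > 100)).any():
                raise ValidationError(f"{col} must lie in [0, 100]")
        for col in _NONNEG_COLUMNS:
            if (df[col].astype(float) < 0).any():
                raise ValidationError(f"{col} must be non-negative")
        self.rows = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)


def write_results(table: ResultsTable, path) -> None:
    """Write a results CSV with fixed column order, 6-decimal floats."""
    table.rows.to_csv(Path(path), index=False, float_format="%.6f")


def read_results(path) -> ResultsTable:
    df = pd.read_csv(Path(path), dtype={"subject_id": str, "eye": str, "timepoint": str})
    return ResultsTable(df)


# ---------------------------------------------------------------------------
# B-scan layer boundaries

BOUNDARY_COLUMNS = ["column", "ilm_row", "rpe_row", "csi_row"]


def write_boundaries(boundaries: pd.DataFrame, path) -> None:
    pd.DataFrame(boundaries, columns=BOUNDARY_COLUMNS).to_csv(
        Path(path), index=False, float_format="%.4f")


def read_boundaries(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = set(BOUNDARY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: boundary CSV missing columns {sorted(missing)}")
    return df[BOUNDARY_COLUMNS]
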