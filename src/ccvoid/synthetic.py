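"""Synthetic angiograms, B-scans and longitudinal study datasets.

Every generator records ground truth (void masks, vessel masks, layer rows,
per-record thickness), giving the analysis pipeline something real patient
scans cannot: a truth channel against which density, count, size and
thickness recovery can be verified exactly.

Speckle model: OCTA en-face texture is speckle-dominated. We draw raw
per-pixel exponential speckle (fully developed speckle intensity), smooth it
with a PSF-sized Gaussian grain, and renormalize the field to mean 1 and the
requested contrast. The smoothing reproduces the spatial grain of real
angiograms; the surviving right skew gives the thin lower intensity tail that
makes mean-minus-1SD thresholding well behaved on perfused tissue.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from . import dataio
from .dataio import EnfaceAngiogram
from .errors import InvalidSpecError
from .masking import BinaryMask, circle_polygon, rasterize_faz
from .thickness import AXIAL_SCALE_UM, BScan

_MAX_SEED = 2 ** 31 - 1


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _MAX_SEED, size=n)


def _speckle_field(shape: tuple, contrast: float, grain_px: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Multiplicative speckle: smoothed exponential field, mean 1, SD=contrast."""
    if contrast <= 0:
        return np.ones(shape)
    raw = rng.exponential(1.0, size=shape)
    if grain_px > 0:
        raw = ndimage.gaussian_filter(raw, grain_px, mode="reflect")
    sd = raw.std()
    if sd == 0:
        return np.ones(shape)
    return np.clip(1.0 + (raw - raw.mean()) * (contrast / sd), 0.0, None)


def _quantize(levels: np.ndarray) -> np.ndarray:
    """8-bit quantization identical to the I/O path, back on [0, 1]."""
    return np.round(np.clip(levels, 0.0, 255.0)).astype(np.uint8) / 255.0


# ---------------------------------------------------------------------------
# specs


@dataclass
class CCSpec:
    """Parameters of a synthetic choriocapillaris slab.

    Defaults mirror a 3 x 3-mm field sampled at 300 px (10 µm/px) with a 16%
    dropout fraction and ~360 µm² target mean void size — the regime reported
    for healthy maculae. ``void_mean_size_um2`` is the target size of
    inserted blobs; merged blobs are legitimate, and realized truth is
    recomputed from the final mask.
    """

    grid_size: int = 300
    lateral_scale_um: float = 10.0
    void_fraction: float = 0.16
    void_mean_size_um2: float = 360.0
    speckle_contrast: float = 0.2
    speckle_grain_px: float = 1.0
    background_level: float = 160.0
    void_level: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.void_fraction < 1.0:
            raise InvalidSpecError("void_fraction must lie in [0, 1)")
        if self.void_level >= self.background_level:
            raise InvalidSpecError("void_level must be below background_level")
        if self.grid_size < 32:
            raise InvalidSpecError("grid_size must be at least 32")
        if self.void_mean_size_um2 <= 0 or self.lateral_scale_um <= 0:
            raise InvalidSpecError("sizes and scales must be positive")
        if not 0.0 <= self.speckle_contrast < 1.0:
            raise InvalidSpecError("speckle_contrast must lie in [0, 1)")


@dataclass
class SVPSpec:
    """Parameters of a synthetic superficial-plexus angiogram.

    ``vessel_fraction`` is the target large-vessel footprint as a fraction of
    the total image; ribbons are carved from a distance transform of smooth
    random centerlines, so the footprint lands on target up to pixel
    quantization. A central circular avascular zone of ``faz_radius_um`` is
    kept capillary- and vessel-free.
    """

    grid_size: int = 300
    lateral_scale_um: float = 10.0
    n_vessels: int = 4
    vessel_fraction: float = 0.10
    vessel_level: float = 230.0
    capillary_level: float = 110.0
    capillary_fill: float = 0.38
    background_level: float = 45.0
    faz_radius_um: float = 300.0
    speckle_contrast: float = 0.2
    speckle_grain_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vessel_fraction < 0.8:
            raise InvalidSpecError("vessel_fraction must lie in [0, 0.8) — "
                                   "larger footprints exceed the image")
        if self.n_vessels < 0 or self.grid_size < 32:
            raise InvalidSpecError("n_vessels >= 0 and grid_size >= 32 required")
        if self.faz_radius_um < 0:
            raise InvalidSpecError("faz_radius_um must be non-negative")


@dataclass
class BScanSpec:
    """Parameters of a synthetic structural B-scan with a foveal pit.

    Rows increase with depth. The ILM dips toward the RPE at the central
    column (Gaussian pit), making the foveal column the one of minimal
    ILM-RPE separation; RPE and CSI are flat bands.
    """

    width: int = 300
    height: int = 420
    ilm_foveal_row: float = 50.0
    pit_depth_px: float = 25.0
    pit_sigma_px: float = 40.0
    rpe_row: float = 164.0
    csi_row: float = 316.0
    axial_scale_um: float = AXIAL_SCALE_UM
    band_sigma_px: float = 1.5
    speckle_contrast: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        peripheral_ilm = self.ilm_foveal_row - self.pit_depth_px
        if self.pit_depth_px < 0:
            raise InvalidSpecError("pit_depth_px must be non-negative")
        if not 0 <= peripheral_ilm:
            raise InvalidSpecError("peripheral ILM row would leave the image")
        if not self.ilm_foveal_row < self.rpe_row < self.csi_row < self.height:
            raise InvalidSpecError(
                "layer ordering ILM < RPE < CSI < height violated")


@dataclass
class StudySpec:
    """A longitudinal diurnal study design with injectable trends.

    Defaults emulate the reference design: 14 subjects, 2 visits, 5
    timepoints at 2-h spacing. Choroidal-thickness defaults reproduce the
    reported diurnal pattern (baseline 297.7 ± 92.1 µm, deltas
    0/−2/−4.1/−2/−3.9 µm); void deltas default to zero (the null that was
    observed). Per-subject thickness baselines are shared across visits;
    measurement noise is within-subject.
    """

    n_subjects: int = 14
    n_visits: int = 2
    timepoints: Sequence[str] = ("09:00", "11:00", "13:00", "15:00", "17:00")
    cc_spec: CCSpec = field(default_factory=CCSpec)
    svp_spec: Optional[SVPSpec] = None
    thickness_baseline_mean: float = 297.7
    thickness_baseline_sd: float = 92.1
    thickness_diurnal_deltas: Sequence[float] = (0.0, -2.0, -4.1, -2.0, -3.9)
    thickness_noise_sd: float = 1.5
    retinal_baseline_mean: float = 222.4
    retinal_baseline_sd: float = 29.0
    retinal_diurnal_deltas: Optional[Sequence[float]] = None
    retinal_noise_sd: float = 1.0
    void_diurnal_deltas: Optional[Sequence[float]] = None
    void_subject_sd: float = 0.01
    grader_noise_sd: float = 9.0
    signal_strengths: Optional[Sequence[float]] = None
    eye: str = "OD"
    bscan_height: int = 0  # 0 = auto from sampled thickness range
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.timepoints)
        if self.n_subjects < 1 or self.n_visits < 1 or k < 1:
            raise InvalidSpecError("counts must be positive")
        if self.retinal_diurnal_deltas is None:
            self.retinal_diurnal_deltas = tuple(0.0 for _ in range(k))
        if self.void_diurnal_deltas is None:
            self.void_diurnal_deltas = tuple(0.0 for _ in range(k))
        for name in ("thickness_diurnal_deltas", "retinal_diurnal_deltas",
                     "void_diurnal_deltas"):
            if len(getattr(self, name)) != k:
                raise InvalidSpecError(f"{name} must have one entry per timepoint")
        for name in ("thickness_baseline_sd", "thickness_noise_sd",
                     "retinal_baseline_sd", "retinal_noise_sd",
                     "void_subject_sd", "grader_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be non-negative")
        if self.signal_strengths is not None:
            n_rec = self.n_subjects * self.n_visits * k
            if len(self.signal_strengths) != n_rec:
                raise InvalidSpecError(
                    f"signal_strengths must have {n_rec} entries (one per record)")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)


@dataclass
class GroundTruth:
    """Truth channel for a generated artifact (fields filled as applicable)."""

    void_mask: Optional[BinaryMask] = None
    true_density_pct: Optional[float] = None
    true_count: Optional[int] = None
    true_mean_size_um2: Optional[float] = None
    large_vessel_mask: Optional[BinaryMask] = None
    faz_polygon: Optional[list] = None
    layer_rows: Optional[pd.DataFrame] = None
    retinal_um: Optional[float] = None
    choroidal_um: Optional[float] = None


# ---------------------------------------------------------------------------
# choriocapillaris


def generate_cc_angiogram(spec: CCSpec):
    """Speckled CC slab with elliptical dropout blobs of known footprint.

    Blobs are placed until the target fraction is reached (stopping within
    one blob), overlap permitted; truth density/count/mean size are
    recomputed from the final mask (8-connectivity), exactly what a perfect
    segmenter would see. Same spec + seed => bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.grid_size
    px_area = spec.lateral_scale_um ** 2
    mean_blob_px = max(spec.void_mean_size_um2 / px_area, 1.0)
    r0 = np.sqrt(mean_blob_px / np.pi)

    mask = np.zeros((n, n), dtype=bool)
    target_px = spec.void_fraction * n * n
    placed = 0
    while placed < target_px:
        cr, cc_ = rng.uniform(0, n, size=2)
        a = r0 * rng.uniform(0.6, 1.5)
        b = r0 * rng.uniform(0.6, 1.5)
        theta = rng.uniform(0, np.pi)
        rr, cc2 = skdraw.ellipse(cr, cc_, a, b, shape=(n, n), rotation=theta)
        if rr.size == 0:
            rr = np.array([min(int(cr), n - 1)])
            cc2 = np.array([min(int(cc_), n - 1)])
        placed += int(np.count_nonzero(~mask[rr, cc2]))
        mask[rr, cc2] = True

    levels = np.where(mask, spec.void_level, spec.background_level)
    speckle = _speckle_field((n, n), spec.speckle_contrast,
                             spec.speckle_grain_px, rng)
    pixels = _quantize(levels * speckle)
    img = EnfaceAngiogram(pixels, "CC", spec.lateral_scale_um)

    void_px = int(mask.sum())
    _, count = ndimage.label(mask, structure=np.ones((3, 3), bool))
    truth = GroundTruth(
        void_mask=BinaryMask(mask, "void"),
        true_density_pct=100.0 * void_px / (n * n),
        true_count=int(count),
        true_mean_size_um2=(void_px * px_area / count) if count else 0.0,
    )
    return img, truth


# ---------------------------------------------------------------------------
# superficial / deep plexus


def _vessel_centerlines(spec: SVPSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterized smooth sinusoid centerlines crossing the field."""
    n = spec.grid_size
    lines = np.zeros((n, n), dtype=bool)
    t = np.arange(n, dtype=float)
    for _ in range(spec.n_vessels):
        base = rng.uniform(0.1 * n, 0.9 * n)
        amp = rng.uniform(0.05 * n, 0.2 * n)
        wavelength = rng.uniform(0.8 * n, 2.5 * n)
        phase = rng.uniform(0, 2 * np.pi)
        path = base + amp * np.sin(2 * np.pi * t / wavelength + phase)
        rows = np.clip(np.round(path).astype(int), 0, n - 1)
        cols = t.astype(int)
        if rng.uniform() < 0.5:
            rows, cols = cols, rows  # half the vessels run vertically
        # connect consecutive samples so the centerline is unbroken
        for i in range(n - 1):
            rr, cc_ = skdraw.line(rows[i], cols[i], rows[i + 1], cols[i + 1])
            lines[rr, cc_] = True
    return lines


def generate_svp_angiogram(spec: SVPSpec):
    """SVP slab: bright large-vessel ribbons, capillary texture, central FAZ.

    Truth records the vessel mask and the FAZ polygon (64-gon). The vessel
    footprint is set by thresholding the distance transform of the
    centerlines at the quantile matching ``vessel_fraction`` of total image
    area, so the realized fraction tracks the request to within pixel
    quantization.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.grid_size
    center = (n / 2.0, n / 2.0)  # (c, r)
    faz_r_px = spec.faz_radius_um / spec.lateral_scale_um
    faz_polygon = circle_polygon(center[0], center[1], faz_r_px) if faz_r_px > 0 else []
    faz_mask = rasterize_faz(faz_polygon, (n, n)).pixels

    vessel_mask = np.zeros((n, n), dtype=bool)
    if spec.n_vessels > 0 and spec.vessel_fraction > 0:
        lines = _vessel_centerlines(spec, rng)
        if lines.any():
            dist = ndimage.distance_transform_edt(~lines)
            outside = ~faz_mask
            want_px = spec.vessel_fraction * n * n
            q = min(want_px / max(int(outside.sum()), 1), 1.0)
            thr = np.quantile(dist[outside], q)
            vessel_mask = (dist <= thr) & outside

    # capillary texture: band-pass noise thresholded to a plexus-like mesh
    field_noise = rng.normal(size=(n, n))
    cap = (ndimage.gaussian_filter(field_noise, 1.0)
           - ndimage.gaussian_filter(field_noise, 3.0))
    cap_mask = cap > np.quantile(cap, 1.0 - spec.capillary_fill)
    cap_mask &= ~faz_mask & ~vessel_mask

    levels = np.full((n, n), spec.background_level)
    levels[cap_mask] = spec.capillary_level
    levels[vessel_mask] = spec.vessel_level
    speckle = _speckle_field((n, n), spec.speckle_contrast,
                             spec.speckle_grain_px, rng)
    pixels = _quantize(levels * speckle)
    img = EnfaceAngiogram(pixels, "SVP", spec.lateral_scale_um)
    truth = GroundTruth(
        large_vessel_mask=BinaryMask(vessel_mask, "large_vessel"),
        faz_polygon=faz_polygon,
    )
    return img, truth


def generate_dvp_angiogram(spec: SVPSpec):
    """Deep-plexus slab: capillary mesh only (projection artifacts assumed
    removed upstream, as done in the device software)."""
    dvp_spec = replace(spec, n_vessels=0, vessel_fraction=0.0,
                       capillary_fill=min(spec.capillary_fill * 0.7, 0.9))
    img, truth = generate_svp_angiogram(dvp_spec)
    img = EnfaceAngiogram(img.pixels, "DVP", spec.lateral_scale_um)
    return img, truth


# ---------------------------------------------------------------------------
# structural B-scans


def layer_rows_from_spec(spec: BScanSpec) -> pd.DataFrame:
    cols = np.arange(spec.width)
    fovea = spec.width / 2.0
    pit = np.exp(-((cols - fovea) ** 2) / (2 * spec.pit_sigma_px ** 2))
    ilm = spec.ilm_foveal_row - spec.pit_depth_px * (1.0 - pit)
    return pd.DataFrame({
        "column": cols,
        "ilm_row": ilm,
        "rpe_row": np.full(spec.width, spec.rpe_row),
        "csi_row": np.full(spec.width, spec.csi_row),
    })


def generate_bscan(spec: BScanSpec):
    """Structural B-scan with bright bands at ILM, RPE and CSI.

    Truth holds the per-column boundary rows and the foveal-column
    thicknesses ((RPE − ILM) and (CSI − RPE) times the axial scale).
    """
    rng = np.random.default_rng(spec.seed)
    rows = layer_rows_from_spec(spec)
    ilm = rows["ilm_row"].to_numpy()
    rpe = rows["rpe_row"].to_numpy()
    csi = rows["csi_row"].to_numpy()
    if not (np.all(ilm < rpe) and np.all(rpe < csi)):
        raise InvalidSpecError("layer ordering violated")

    r = np.arange(spec.height)[:, None].astype(float)
    levels = np.full((spec.height, spec.width), 0.04)
    levels = np.where((r >= ilm) & (r < rpe), 0.22, levels)   # retina
    levels = np.where((r >= rpe) & (r < csi), 0.14, levels)   # choroid
    levels = np.where(r >= csi, 0.08, levels)                 # sclera
    for rows_b, amp in ((ilm, 0.65), (rpe, 0.9), (csi, 0.45)):
        levels += amp * np.exp(-((r - rows_b) ** 2) / (2 * spec.band_sigma_px ** 2))
    speckle = _speckle_field(levels.shape, spec.speckle_contrast, 1.0, rng)
    pixels = _quantize(levels * speckle * 255.0)

    bscan = BScan(pixels, spec.axial_scale_um, boundaries=rows)
    fc = spec.width // 2
    truth = GroundTruth(
        layer_rows=rows,
        retinal_um=(rpe[fc] - ilm[fc]) * spec.axial_scale_um,
        choroidal_um=(csi[fc] - rpe[fc]) * spec.axial_scale_um,
    )
    return bscan, truth


# ---------------------------------------------------------------------------
# longitudinal study


def sample_thickness_truths(spec: StudySpec, rng: np.random.Generator) -> pd.DataFrame:
    """Sample per-record thickness truths: baseline_i + delta_t + noise.

    Baselines are per-subject (shared across visits); deltas are
    per-timepoint; noise is iid within subject. Values are clipped to
    anatomically representable ranges.
    """
    records = []
    chor_base = rng.normal(spec.thickness_baseline_mean,
                           spec.thickness_baseline_sd, size=spec.n_subjects)
    ret_base = rng.normal(spec.retinal_baseline_mean,
                          spec.retinal_baseline_sd, size=spec.n_subjects)
    chor_base = np.clip(chor_base, 80.0, 600.0)
    ret_base = np.clip(ret_base, 120.0, 400.0)
    for i in range(spec.n_subjects):
        for v in range(1, spec.n_visits + 1):
            for t, tp in enumerate(spec.timepoints):
                chor = (chor_base[i] + spec.thickness_diurnal_deltas[t]
                        + rng.normal(0.0, spec.thickness_noise_sd))
                ret = (ret_base[i] + spec.retinal_diurnal_deltas[t]
                       + rng.normal(0.0, spec.retinal_noise_sd))
                records.append({
                    "subject_id": f"S{i + 1:02d}", "visit": v, "timepoint": tp,
                    "choroidal_um": float(np.clip(chor, 60.0, 650.0)),
                    "retinal_um": float(np.clip(ret, 100.0, 450.0)),
                })
    return pd.DataFrame(records)


def sample_void_fractions(spec: StudySpec, rng: np.random.Generator) -> pd.DataFrame:
    """Per-record target void fractions: base + subject offset + delta_t."""
    base = spec.cc_spec.void_fraction
    offsets = rng.normal(0.0, spec.void_subject_sd, size=spec.n_subjects)
    records = []
    for i in range(spec.n_subjects):
        for v in range(1, spec.n_visits + 1):
            for t, tp in enumerate(spec.timepoints):
                vf = base + offsets[i] + spec.void_diurnal_deltas[t]
                records.append({
                    "subject_id": f"S{i + 1:02d}", "visit": v, "timepoint": tp,
                    "void_fraction": float(np.clip(vf, 0.0, 0.9)),
                })
    return pd.DataFrame(records)


def simulate_graders(true_values: np.ndarray, n_graders: int = 2,
                     noise_sd: float = 9.0, seed: int = 0) -> np.ndarray:
    """Subjects x graders ratings: truth + iid Gaussian grader noise.

    Emulates independent graders re-measuring the same scans; feeds the
    inter-/intra-grader ICC analysis.
    """
    rng = np.random.default_rng(seed)
    truth = np.asarray(true_values, dtype=float)[:, None]
    return truth + rng.normal(0.0, noise_sd, size=(truth.shape[0], n_graders))


def generate_diurnal_study(spec: StudySpec, out_dir) -> Path:
    """Write a complete synthetic study to ``out_dir``; returns the manifest path.

    Per record (subject x visit x timepoint) the study contains CC, SVP and
    DVP angiograms (8-bit TIFF), a FAZ polygon JSON next to the SVP image, a
    structural B-scan with a boundary-trace CSV, and manifest rows for all
    four slabs. ``truth.csv`` carries the generator's per-record truth.
    Identical spec + seed produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    thickness = sample_thickness_truths(spec, rng)
    fractions = sample_void_fractions(spec, rng)
    n_rec = len(thickness)
    seeds = rng.integers(0, _MAX_SEED, size=(n_rec, 4))

    svp_spec = spec.svp_spec or SVPSpec(
        grid_size=spec.cc_spec.grid_size,
        lateral_scale_um=spec.cc_spec.lateral_scale_um)
    if spec.bscan_height > 0:
        height = spec.bscan_height
    else:
        max_depth_px = 50 + int(np.ceil(
            (thickness["retinal_um"] + thickness["choroidal_um"]).max()
            / AXIAL_SCALE_UM))
        height = max_depth_px + 40

    if spec.signal_strengths is None:
        strengths = np.full(n_rec, 10.0)
    else:
        strengths = np.asarray(spec.signal_strengths, dtype=float)

    manifest_rows = []
    truth_rows = []
    for idx in range(n_rec):
        meta = thickness.iloc[idx]
        vf = float(fractions.iloc[idx]["void_fraction"])
        sid, visit, tp = meta["subject_id"], int(meta["visit"]), meta["timepoint"]
        stem = f"{sid}_v{visit}_{tp.replace(':', '')}"

        cc_img, cc_truth = generate_cc_angiogram(
            replace(spec.cc_spec, void_fraction=vf, seed=int(seeds[idx, 0])))
        svp_img, svp_truth = generate_svp_angiogram(
            replace(svp_spec, seed=int(seeds[idx, 1])))
        dvp_img, _ = generate_dvp_angiogram(
            replace(svp_spec, seed=int(seeds[idx, 2])))

        ret_px = max(round(meta["retinal_um"] / AXIAL_SCALE_UM), 10)
        cho_px = max(round(meta["choroidal_um"] / AXIAL_SCALE_UM), 10)
        bspec = BScanSpec(
            width=spec.cc_spec.grid_size, height=height,
            ilm_foveal_row=50.0, rpe_row=50.0 + ret_px,
            csi_row=50.0 + ret_px + cho_px, seed=int(seeds[idx, 3]))
        bscan, bscan_truth = generate_bscan(bspec)

        paths = {
            "CC": f"{stem}_cc.tiff", "SVP": f"{stem}_svp.tiff",
            "DVP": f"{stem}_dvp.tiff", "BSCAN": f"{stem}_bscan.tiff",
        }
        dataio.write_angiogram(cc_img, out / paths["CC"])
        dataio.write_angiogram(svp_img, out / paths["SVP"])
        dataio.write_angiogram(dvp_img, out / paths["DVP"])
        dataio.write_image(bscan.pixels, out / paths["BSCAN"])
        dataio.write_polygon(svp_truth.faz_polygon, out / f"{stem}_svp_faz.json")
        dataio.write_boundaries(bscan.boundaries, out / f"{stem}_bscan_boundaries.csv")

        for slab, fname in paths.items():
            manifest_rows.append({
                "subject_id": sid, "eye": spec.eye, "visit": visit,
                "timepoint": tp, "slab": slab, "path": fname,
                "signal_strength": float(strengths[idx]),
            })
        truth_rows.append({
            "subject_id": sid, "eye": spec.eye, "visit": visit, "timepoint": tp,
            "true_void_fraction": vf,
            "true_void_density_pct": cc_truth.true_density_pct,
            "true_void_count": cc_truth.true_count,
            "true_void_mean_size_um2": cc_truth.true_mean_size_um2,
            "true_vessel_fraction":
                svp_truth.large_vessel_mask.area_px() / svp_img.pixels.size,
            "true_retinal_um": meta["retinal_um"],
            "true_choroidal_um": meta["choroidal_um"],
        })

    manifest = dataio.StudyManifest(pd.DataFrame(manifest_rows), base_dir=out)
    manifest_path = out / "manifest.csv"
    dataio.write_manifest(manifest, manifest_path)
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False,
                                    float_format="%.6f")
    return manifest_path
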