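"""ROI definition, rasterization and per-ROI / per-patient summaries.

Tumor and normal-kidney regions are polygonal ROIs drawn per slice;
individual biopsies are sampled with cylindrical ROIs of 3 cm diameter
and height centered on the recorded biopsy position.  Rasterization uses
the voxel-center convention: a voxel belongs to an ROI iff its center —
at physical position ``(index + 0.5) * voxel_size`` mm, 0-based indices —
lies inside the polygon (boundary inclusive) or within the cylinder
radius/half-height (both inclusive).

Biopsy physical coordinates come from the patient-specific tumor-mold
co-registration and are consumed as given; per-patient summaries take the
median over a patient's biopsies after excluding samples with less than
75% viable tumor tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .coil_combination import MetaboliteMaps
from .kinetics import NoiseEstimate, compute_snr, lac_pyr_ratio
from .synthetic_data import AcquisitionGeometry

logger = logging.getLogger("hp13c")

__all__ = ["ROIDefinition", "ROISummary", "rasterize_roi", "summarize_roi",
           "patient_level_table", "VIABLE_FRACTION_MIN"]

#: biopsies below this viable-tumor fraction are excluded (strictly below)
VIABLE_FRACTION_MIN = 0.75


@dataclass
class ROIDefinition:
    """A polygonal or cylindrical region of interest in physical mm.

    ``polygon`` maps slice index -> ordered (row_mm, col_mm) vertex list
    (>= 3 vertices, non-self-intersecting).  ``cylinder_center_mm`` is
    (z_mm, row_mm, col_mm); alternatively ``cylinder_center_voxel`` gives
    (slice, row, col) indices converted with the voxel-center convention.
    """

    kind: str                       # "polygon" | "cylinder"
    label: str = ""
    polygon: dict[int, list[tuple[float, float]]] = field(default_factory=dict)
    cylinder_center_mm: tuple[float, float, float] | None = None
    cylinder_center_voxel: tuple[int, int, int] | None = None
    diameter_mm: float = 30.0
    height_mm: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("polygon", "cylinder"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "polygon":
            if not self.polygon:
                raise ValueError("polygon ROI needs at least one slice outline")
            for s, verts in self.polygon.items():
                if len(verts) < 3:
                    raise ValueError(f"slice {s}: polygon needs >= 3 vertices")
                ring = shapely.LinearRing(verts)
                if not ring.is_simple:
                    raise ValueError(f"slice {s}: polygon is self-intersecting")
        else:
            if self.cylinder_center_mm is None and self.cylinder_center_voxel is None:
                raise ValueError("cylinder ROI needs a center")

    def center_mm(self, geometry: AcquisitionGeometry) -> tuple[float, float, float]:
        if self.cylinder_center_mm is not None:
            return self.cylinder_center_mm
        s, r, c = self.cylinder_center_voxel
        vy, vx = geometry.voxel_size_mm
        z = s * geometry.slice_pitch_mm + geometry.slice_thickness * 10.0 / 2.0
        return (z, (r + 0.5) * vy, (c + 0.5) * vx)


def _voxel_centers_mm(geometry: AcquisitionGeometry):
    ny, nx = geometry.recon_matrix
    vy, vx = geometry.voxel_size_mm
    rows = (np.arange(ny) + 0.5) * vy
    cols = (np.arange(nx) + 0.5) * vx
    z = np.arange(geometry.n_slices) * geometry.slice_pitch_mm \
        + geometry.slice_thickness * 10.0 / 2.0
    return z, rows, cols


def rasterize_roi(roi: ROIDefinition, geometry: AcquisitionGeometry) -> np.ndarray:
    """Boolean voxel mask of the ROI on the reconstruction grid.

    Polygon: voxel centers inside or on the outline (even-odd rule for the
    simple polygons accepted by the constructor).  Cylinder: in-plane
    center distance <= radius and slice center within half the height of
    the cylinder center, both inclusive.  An ROI extending beyond the FOV
    raises; an ROI covering no voxel centers warns and returns an empty
    mask.
    """
    z, rows, cols = _voxel_centers_mm(geometry)
    fov_mm = geometry.fov * 10.0
    mask = np.zeros((geometry.n_slices, rows.size, cols.size), dtype=bool)

    if roi.kind == "polygon":
        for s, verts in roi.polygon.items():
            arr = np.asarray(verts, dtype=float)
            if arr.min() < 0 or arr.max() > fov_mm:
                raise ValueError(f"slice {s}: polygon extends beyond the FOV")
            poly = shapely.Polygon(arr)
            rr, cc = np.meshgrid(rows, cols, indexing="ij")
            inside = shapely.intersects_xy(poly, rr.ravel(), cc.ravel())
            mask[s] = inside.reshape(rr.shape)
    else:
        zc, rc, cc_ = roi.center_mm(geometry)
        radius = roi.diameter_mm / 2.0
        if not (0 <= rc <= fov_mm and 0 <= cc_ <= fov_mm):
            raise ValueError("cylinder center outside the FOV")
        in_slice = np.abs(z - zc) <= roi.height_mm / 2.0
        rr, ccg = np.meshgrid(rows, cols, indexing="ij")
        in_plane = (rr - rc) ** 2 + (ccg - cc_) ** 2 <= radius**2
        mask[in_slice] = in_plane

    if not mask.any():
        logger.warning("ROI %r rasterized to an empty mask", roi.label)
    return mask


@dataclass
class ROISummary:
    """Per-ROI statistics of the kPL map and metabolite maps."""

    label: str
    patient_id: str
    n_voxels: int
    kpl_median: float            # NaN when no fitted voxels
    kpl_range: tuple[float, float]
    lac_pyr: float
    snr_pyruvate: float
    snr_lactate: float
    snr_total_carbon: float

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("a summary requires at least one voxel")
        lo, hi = self.kpl_range
        if np.isfinite(self.kpl_median) and not (lo <= self.kpl_median <= hi):
            raise ValueError("range must contain the median")


def summarize_roi(
    mask: np.ndarray,
    kpl_map: np.ndarray,
    maps: MetaboliteMaps,
    noise: NoiseEstimate,
    label: str = "",
    patient_id: str = "",
    noise_lactate: NoiseEstimate | None = None,
    noise_total: NoiseEstimate | None = None,
) -> ROISummary:
    """Median/range kPL, Lac/Pyr and per-metabolite SNR over a masked ROI.

    ``noise`` is used for the pyruvate map; separate background estimates
    for the lactate and total-carbon maps may be supplied (they share the
    mask geometry but not necessarily the same statistics).  If no fitted
    kPL voxels fall inside the mask the kPL fields are NaN and a warning
    is emitted.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    vals = np.asarray(kpl_map)[mask]
    fitted = vals[np.isfinite(vals)]
    if fitted.size:
        kmed = float(np.median(fitted))
        krange = (float(fitted.min()), float(fitted.max()))
    else:
        logger.warning("ROI %r: no fitted voxels in mask", label)
        kmed, krange = float("nan"), (float("nan"), float("nan"))
    return ROISummary(
        label=label,
        patient_id=patient_id,
        n_voxels=int(mask.sum()),
        kpl_median=kmed,
        kpl_range=krange,
        lac_pyr=lac_pyr_ratio(maps, mask),
        snr_pyruvate=compute_snr(maps.pyruvate[mask], noise),
        snr_lactate=compute_snr(maps.lactate[mask], noise_lactate or noise),
        snr_total_carbon=compute_snr(maps.total_carbon[mask], noise_total or noise),
    )


def patient_level_table(
    biopsy_table: pd.DataFrame,
    viable_min: float = VIABLE_FRACTION_MIN,
) -> tuple[pd.DataFrame, int]:
    """Per-patient medians of biopsy-level measurements.

    Biopsies with ``viable_fraction`` strictly below ``viable_min`` are
    excluded first (a fraction exactly at the threshold is retained); then
    medians of kpl, mct1_pct, mct4_pct and cell_density are taken per
    patient to compensate for spatially heterogeneous expression.  Returns
    the patient table and the number of excluded biopsies.  Patients whose
    biopsies are all excluded keep a row of NaNs (with a warning).
    """
    required = {"patient_id", "viable_fraction"}
    missing = required - set(biopsy_table.columns)
    if missing:
        raise ValueError(f"biopsy table lacks columns {sorted(missing)}")
    value_cols = [c for c in ("kpl", "mct1_pct", "mct4_pct", "cell_density")
                  if c in biopsy_table.columns]
    keep = biopsy_table["viable_fraction"] >= viable_min
    n_excluded = int((~keep).sum())
    kept = biopsy_table[keep]
    grouped = kept.groupby("patient_id")[value_cols].median()
    counts = kept.groupby("patient_id").size().rename("n_biopsies")
    out = grouped.join(counts, how="outer")

    all_patients = biopsy_table["patient_id"].unique()
    out = out.reindex(all_patients)
    empty = out["n_biopsies"].isna()
    if empty.any():
        for pid in out.index[empty]:
            logger.warning("patient %s: no biopsies survive the viable-tissue "
                           "filter", pid)
        out.loc[empty, "n_biopsies"] = 0
    out["n_biopsies"] = out["n_biopsies"].astype(int)
    out = out.reset_index().rename(columns={"index": "patient_id"})
    return out, n_excluded
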