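"""DAB immunohistochemistry quantification via optical-density classes.

Implements the area-quantification readout used for MCT1/MCT4 scoring:
RGB micrographs are converted to optical density (Beer-Lambert), separated
into hematoxylin and DAB contributions by least-squares color
deconvolution, and every tissue pixel is binned as negative/weak/moderate/
strong using the published OD thresholds 0.2164, 0.3274 and 0.4938.
Percent positive tissue is the weak+moderate+strong area over the tissue
area; cell density divides a connected-component nucleus count by the
tissue area.

The tissue rule (total OD >= a floor) and the nucleus counter (8-connected
components above a hematoxylin OD threshold) are deliberately simple,
explicit substitutes for proprietary commercial operators; they are exact
on the synthetic micrographs this package generates and would need
calibration on scanner data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger("hp13c")

__all__ = [
    "STAIN_OD_HEMATOXYLIN",
    "STAIN_OD_DAB",
    "StainClassifier",
    "IHCQuantResult",
    "rgb_to_od",
    "deconvolve_stains",
    "classify_pixels",
    "percent_positive",
    "count_cells",
    "quantify_image",
    "CLASS_NAMES",
]

# Standard H-DAB stain direction vectors (unit optical-density directions,
# R/G/B order), after Ruifrok & Johnston's color-deconvolution calibration.
STAIN_OD_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
STAIN_OD_HEMATOXYLIN = STAIN_OD_HEMATOXYLIN / np.linalg.norm(STAIN_OD_HEMATOXYLIN)
STAIN_OD_DAB = np.array([0.268, 0.570, 0.776])
STAIN_OD_DAB = STAIN_OD_DAB / np.linalg.norm(STAIN_OD_DAB)

CLASS_NAMES = ("negative", "weak", "moderate", "strong")

#: integer code for pixels outside the tissue mask in a class map
NOT_TISSUE = -1

_OD_CAP = 3.0  # OD assigned to zero-intensity pixels


@dataclass(frozen=True)
class StainClassifier:
    """OD thresholds and stain geometry for DAB positivity scoring.

    ``od_thresholds`` are the lower bounds of the weak, moderate and strong
    classes (inclusive).  ``tissue_od_floor`` defines tissue as any pixel
    whose total (Euclidean) OD reaches the floor.
    """

    od_thresholds: dict = field(default_factory=lambda: {
        "weak": 0.2164, "moderate": 0.3274, "strong": 0.4938,
    })
    hematoxylin: np.ndarray = field(
        default_factory=lambda: STAIN_OD_HEMATOXYLIN.copy())
    dab: np.ndarray = field(default_factory=lambda: STAIN_OD_DAB.copy())
    tissue_od_floor: float = 0.05
    white_reference: float = 255.0

    def __post_init__(self) -> None:
        w = self.od_thresholds["weak"]
        m = self.od_thresholds["moderate"]
        s = self.od_thresholds["strong"]
        if not 0 < w < m < s:
            raise ValueError("thresholds must satisfy 0 < weak < moderate < strong")
        for v in (self.hematoxylin, self.dab):
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
                raise ValueError("stain vectors must be unit-norm")
        cosang = abs(float(self.hematoxylin @ self.dab))
        if cosang > 1.0 - 1e-6:
            raise ValueError("stain vectors are collinear")

    @property
    def threshold_array(self) -> np.ndarray:
        t = self.od_thresholds
        return np.array([t["weak"], t["moderate"], t["strong"]])


@dataclass
class IHCQuantResult:
    """Area-fraction and cell-density summary of one stained section."""

    percent_positive: float
    class_fractions: dict            # negative/weak/moderate/strong, of tissue
    tissue_area: int                 # pixels
    cell_count: int
    cell_density: float              # cells per tissue pixel

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class fractions must partition the tissue area")
        if not 0.0 <= self.percent_positive <= 100.0:
            raise ValueError("percent_positive must be within [0, 100]")


def rgb_to_od(image: np.ndarray, white_reference: float = 255.0) -> np.ndarray:
    """Per-channel optical density, OD_c = -log10(I_c / I0).

    Zero-intensity pixels are clamped to OD 3.0 (their count is logged);
    pure white maps to 0.
    """
    img = np.asarray(image, dtype=float)
    n_zero = int(np.count_nonzero(img <= 0))
    if n_zero:
        logger.info("rgb_to_od: clamping %d zero-intensity values to OD %.1f",
                    n_zero, _OD_CAP)
    ratio = np.clip(img, 10.0 ** (-_OD_CAP) * white_reference, white_reference)
    return -np.log10(ratio / white_reference)


def deconvolve_stains(
    od_image: np.ndarray,
    classifier: StainClassifier | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a 3-channel OD image into hematoxylin and DAB concentrations.

    Least-squares projection of each pixel's OD vector onto the two stain
    directions; negative concentrations are clipped to zero (count logged).
    """
    classifier = classifier or StainClassifier()
    A = np.stack([classifier.hematoxylin, classifier.dab], axis=1)  # (3, 2)
    if np.linalg.cond(A) > 1e6:
        raise ValueError("stain vectors are too close to collinear")
    pinv = np.linalg.pinv(A)                                         # (2, 3)
    conc = np.einsum("sc,...c->...s", pinv, od_image)
    n_neg = int(np.count_nonzero(conc < 0))
    if n_neg:
        logger.debug("deconvolve_stains: clipping %d negative concentrations", n_neg)
    conc = np.maximum(conc, 0.0)
    return conc[..., 0], conc[..., 1]


def classify_pixels(
    dab_od: np.ndarray,
    classifier: StainClassifier | None = None,
    tissue_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Class map over the tissue: 0 negative, 1 weak, 2 moderate, 3 strong.

    Boundaries are inclusive lower bounds: OD exactly at a threshold takes
    the higher class.  Pixels outside the tissue mask get ``NOT_TISSUE``.
    """
    classifier = classifier or StainClassifier()
    cls = np.digitize(dab_od, classifier.threshold_array, right=False)
    cls = cls.astype(np.int8)
    if tissue_mask is not None:
        cls = np.where(tissue_mask, cls, NOT_TISSUE)
    return cls


def percent_positive(class_map: np.ndarray) -> tuple[float, dict]:
    """Percent positive tissue and the per-class area fractions.

    Positive = weak + moderate + strong pixels over tissue pixels, as a
    percentage.  Raises on an empty tissue mask.
    """
    tissue = class_map >= 0
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("empty tissue mask")
    fractions = {
        name: int(np.count_nonzero(class_map == code)) / n_tissue
        for code, name in enumerate(CLASS_NAMES)
    }
    pct = 100.0 * (1.0 - fractions["negative"])
    return pct, fractions


def count_cells(
    hema_od: np.ndarray,
    min_od: float = 0.5,
    min_area: int = 4,
) -> int:
    """Count nuclei as 8-connected components of strong hematoxylin.

    Components with hematoxylin OD >= ``min_od`` and at least ``min_area``
    pixels are counted.
    """
    if min_od <= 0 or min_area <= 0:
        raise ValueError("min_od and min_area must be positive")
    binary = np.asarray(hema_od) >= min_od
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    return int(np.count_nonzero(sizes >= min_area))


def quantify_image(
    rgb: np.ndarray,
    classifier: StainClassifier | None = None,
    min_nucleus_od: float = 0.5,
    min_nucleus_area: int = 4,
) -> IHCQuantResult:
    """Full quantification of one RGB micrograph.

    Chains OD conversion, stain deconvolution, tissue detection (total OD
    floor), classification, area fractions and nucleus counting.
    """
    classifier = classifier or StainClassifier()
    od = rgb_to_od(rgb, classifier.white_reference)
    tissue = np.linalg.norm(od, axis=-1) >= classifier.tissue_od_floor
    hema, dab = deconvolve_stains(od, classifier)
    cls = classify_pixels(dab, classifier, tissue_mask=tissue)
    pct, fractions = percent_positive(cls)
    cells = count_cells(np.where(tissue, hema, 0.0),
                        min_od=min_nucleus_od, min_area=min_nucleus_area)
    tissue_area = int(tissue.sum())
    return IHCQuantResult(
        percent_positive=pct,
        class_fractions=fractions,
        tissue_area=tissue_area,
        cell_count=cells,
        cell_density=cells / tissue_area,
    )
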