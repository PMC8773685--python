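"""SVD coil combination and time-summed metabolite maps.

Multi-channel complex 13C data are combined into a single channel using a
per-voxel matched filter derived from a singular value decomposition of
the time-summed data: summing the complex frames first concentrates the
signal and minimizes noise propagation into the weights, and the dominant
right-singular vector of the (metabolite x neighborhood) x coil matrix is
the maximum-SNR combination direction when the noise covariance is
identity (no pre-whitening step is applied; the simulator draws white
noise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic_data import AcquisitionGeometry, DynamicMetabolicImage

logger = logging.getLogger("hp13c")

__all__ = ["CoilWeights", "MetaboliteMaps", "compute_weights", "apply_weights",
           "sum_time_maps"]


@dataclass
class CoilWeights:
    """Per-voxel unit-norm complex coil weights.

    The phase convention makes the weight of ``reference_coil`` real and
    non-negative at every voxel, fixing the overall phase ambiguity of the
    singular vector.
    """

    weights: np.ndarray          # (n_coils, n_slices, ny, nx) complex
    reference_coil: int = 0

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.weights, axis=0)
        if not np.allclose(norms[norms > 0], 1.0, atol=1e-8):
            raise ValueError("weight vectors must have unit Euclidean norm")


@dataclass
class MetaboliteMaps:
    """Time-summed magnitude maps on the reconstruction grid.

    ``total_carbon`` is the voxel-wise sum of the pyruvate and lactate
    maps (pyruvate + lactate), computed after taking magnitudes.
    """

    pyruvate: np.ndarray        # (n_slices, ny, nx), >= 0
    lactate: np.ndarray
    total_carbon: np.ndarray
    provenance: str = "time-summed-then-combined"

    def __post_init__(self) -> None:
        for arr in (self.pyruvate, self.lactate, self.total_carbon):
            if np.any(arr < 0):
                raise ValueError("metabolite maps must be non-negative")
        if not np.allclose(self.total_carbon, self.pyruvate + self.lactate,
                           rtol=1e-10, atol=1e-12):
            raise ValueError("total carbon must equal pyruvate + lactate")

    def __getitem__(self, name: str) -> np.ndarray:
        return {"pyruvate": self.pyruvate, "lactate": self.lactate,
                "total_carbon": self.total_carbon}[name]


def compute_weights(
    image: DynamicMetabolicImage,
    neighborhood: int = 1,
    reference_coil: int = 0,
) -> CoilWeights:
    """Derive per-voxel coil weights from time-summed complex data.

    For every voxel a matrix is formed whose rows are the time-summed
    complex values of both metabolites over a square in-plane neighborhood
    (default 1x1) and whose columns are coils; the weight vector is its
    dominant right-singular vector under the reference-coil phase
    convention.  Voxels with all-zero data fall back to a unit weight on
    the reference coil.
    """
    if neighborhood < 1 or neighborhood % 2 == 0 and neighborhood != 1:
        raise ValueError("neighborhood must be 1 or an odd integer >= 1")
    g = image.geometry
    n_coils = g.n_coils
    if not 0 <= reference_coil < n_coils:
        raise ValueError("reference_coil out of range")

    summed = image.data.sum(axis=2)           # (2, C, S, Y, X)
    ns, ny, nx = summed.shape[2:]

    if neighborhood == 1:
        # rows: metabolites; batched SVD over voxels
        mats = np.transpose(summed, (2, 3, 4, 0, 1)).reshape(-1, 2, n_coils)
    else:
        k = neighborhood // 2
        padded = np.pad(summed, ((0, 0), (0, 0), (0, 0), (k, k), (k, k)))
        # gather (2, C, S, Y, X, nh, nh) windows
        windows = np.lib.stride_tricks.sliding_window_view(
            padded, (neighborhood, neighborhood), axis=(3, 4))
        mats = np.transpose(windows, (2, 3, 4, 0, 5, 6, 1)).reshape(
            -1, 2 * neighborhood * neighborhood, n_coils)

    # Rank-1 data rows are rho_i * s, so vh[0] equals s up to scale/phase;
    # taking w = vh[0] makes the later conj(w) inner product the matched
    # filter s^H / ||s||.
    _, _, vh = np.linalg.svd(mats, full_matrices=False)
    w = vh[:, 0, :]                           # (N, C), unit norm

    zero = ~np.any(mats != 0, axis=(1, 2))
    if np.any(zero):
        w[zero] = 0.0
        w[zero, reference_coil] = 1.0

    # phase convention: reference-coil weight real, non-negative
    ref = w[:, reference_coil]
    phase = np.exp(-1j * np.angle(ref, deg=False))
    phase[ref == 0] = 1.0
    w = w * phase[:, None]

    weights = np.transpose(w.reshape(ns, ny, nx, n_coils), (3, 0, 1, 2))
    return CoilWeights(weights=weights, reference_coil=reference_coil)


def apply_weights(
    image: DynamicMetabolicImage,
    weights: CoilWeights,
) -> np.ndarray:
    """Combine coils: per voxel/frame/metabolite the inner product with conj(w).

    Returns a complex array of shape (2, n_frames, n_slices, ny, nx); the
    time axis of the input is unchanged.
    """
    if weights.weights.shape != (image.geometry.n_coils,
                                 *image.data.shape[3:]):
        raise ValueError("weight grid does not match image grid")
    return np.einsum("mcfsyx,csyx->mfsyx", image.data, weights.weights.conj())


def sum_time_maps(combined: np.ndarray) -> MetaboliteMaps:
    """Time-summed metabolite maps from a combined dynamic image.

    The complex data are summed over frames first and the magnitude taken
    last; total carbon is the voxel-wise sum of the two magnitude maps.
    """
    if combined.ndim != 5 or combined.shape[0] != 2:
        raise ValueError("expected combined image of shape (2, F, S, Y, X)")
    summed = np.abs(combined.sum(axis=1))
    pyr, lac = summed[0], summed[1]
    return MetaboliteMaps(pyruvate=pyr, lactate=lac, total_carbon=pyr + lac)
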