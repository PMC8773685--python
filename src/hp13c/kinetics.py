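"""Metabolite SNR, SNR masking and kPL estimation.

SNR follows the magnitude-image convention

    SNR = (mean(SI_ROI) - mean(SI_noise)) / (sqrt(2) * SD(SI_noise))

where the noise statistics come from an extracorporeal background region;
the sqrt(2) accounts for the narrowed Rayleigh distribution of magnitude
noise.  Voxels enter the kinetic fit only where the time-summed total
carbon SNR is at least 5 (inclusive).

kPL is estimated from the lactate balance of the two-site exchange model,

    dL/dt = kPL * P - L / T1eff,

by a frequency-domain linear least-squares fit: the N-1 trapezoid
difference/average sequences of the sampled courses are Fourier
transformed (4x zero-padded) and the resulting overdetermined complex
system is solved for (kPL, 1/T1eff) over stacked real and imaginary
parts.  Forming the system from interval differences — rather than
applying the continuous derivative theorem to the raw window — handles
the acquisition window exactly: the signal is already large at the first
frame (12 s after injection) and a periodic-extension treatment of the
raw courses is badly biased by the window boundary terms.

When the per-sample noise SD is known, a moment (errors-in-variables)
correction is subtracted from the normal equations; without it the noisy
lactate regressor attenuates both rate estimates.  A time-domain
nonlinear fit of the explicit convolution solution serves as an
independent verification oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .coil_combination import MetaboliteMaps

logger = logging.getLogger("hp13c")

__all__ = [
    "NoiseEstimate",
    "KineticFitResult",
    "KplMapResult",
    "estimate_noise",
    "compute_snr",
    "build_fit_mask",
    "fit_kpl_frequency_domain",
    "fit_kpl_time_domain_oracle",
    "lac_pyr_ratio",
    "fit_kpl_map",
    "phase_corrected_real",
]

SNR_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class NoiseEstimate:
    """Background magnitude-noise statistics from an extracorporeal region."""

    mean_noise: float
    sd_noise: float
    n_voxels: int = 0
    source: str = "extracorporeal"

    def __post_init__(self) -> None:
        if self.sd_noise <= 0:
            raise ValueError("sd_noise must be positive")

    def component_sd(self, n_frames: int) -> float:
        """Per-frame, per-component Gaussian noise SD implied by the summed map.

        For complex Gaussian noise the summed-map background magnitude is
        Rayleigh with component sigma_s, so SD = sigma_s*sqrt(2 - pi/2) and
        sigma_s = sqrt(n_frames) * sigma_frame.
        """
        sigma_s = self.sd_noise / math.sqrt(2.0 - math.pi / 2.0)
        return sigma_s / math.sqrt(n_frames)


def estimate_noise(
    background_values: np.ndarray,
    min_voxels: int = 100,
    source: str = "extracorporeal",
) -> NoiseEstimate:
    """Mean/SD noise estimate from background magnitude samples."""
    vals = np.asarray(background_values, dtype=float).ravel()
    if vals.size < min_voxels:
        raise ValueError(
            f"need >= {min_voxels} background voxels, got {vals.size}"
        )
    return NoiseEstimate(mean_noise=float(vals.mean()),
                         sd_noise=float(vals.std(ddof=1)),
                         n_voxels=vals.size, source=source)


def compute_snr(roi_values: np.ndarray, noise: NoiseEstimate) -> float:
    """Magnitude SNR of an ROI: (mean(ROI) - mean_noise) / (sqrt(2)*sd_noise).

    May be negative; raises on an empty ROI.
    """
    vals = np.asarray(roi_values, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("empty ROI")
    return float((vals.mean() - noise.mean_noise) / (SNR_SQRT2 * noise.sd_noise))


def build_fit_mask(
    total_carbon_map: np.ndarray,
    noise: NoiseEstimate,
    threshold: float = 5.0,
) -> np.ndarray:
    """Voxels whose single-voxel total-carbon SNR is >= threshold (inclusive)."""
    snr = (np.asarray(total_carbon_map, dtype=float) - noise.mean_noise) / (
        SNR_SQRT2 * noise.sd_noise
    )
    return snr >= threshold


# --------------------------------------------------------------------------
# kPL estimation
# --------------------------------------------------------------------------

FLAG_NEGATIVE_KPL = "negative_kpl"
FLAG_NEGATIVE_RATE = "negative_inv_t1_eff"
FLAG_ZERO_LACTATE = "zero_lactate"


@dataclass
class KineticFitResult:
    """A fitted (kPL, 1/T1eff) pair with diagnostics.

    Negative solutions are reported as-is and flagged, never clipped.
    """

    k_pl_hat: float
    inv_t1_eff_hat: float
    residual_norm: float
    n_frames_used: int
    method: str
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k_pl_hat) and np.isfinite(self.inv_t1_eff_hat)):
            raise ValueError("fitted parameters must be finite")
        if self.residual_norm < 0:
            raise ValueError("residual norm must be >= 0")

    @property
    def t1_eff_hat(self) -> float:
        return 1.0 / self.inv_t1_eff_hat if self.inv_t1_eff_hat != 0 else math.inf


def _difference_system(pyr: np.ndarray, lac: np.ndarray, dt: float):
    """Trapezoid interval differences/averages of the sampled courses.

    Valid model equations: dL_k/dt = kPL * Pa_k - r * La_k for the N-1
    frame intervals (no periodic wrap across the acquisition window).
    Works on batches: inputs (..., N) give outputs (..., N-1).
    """
    dL = np.diff(lac, axis=-1) / dt
    Pa = 0.5 * (pyr[..., :-1] + pyr[..., 1:])
    La = 0.5 * (lac[..., :-1] + lac[..., 1:])
    return dL, Pa, La


def _solve_freq_domain(dL, Pa, La, dt, noise_sd, zero_pad=4):
    """Solve the frequency-domain system for batches of courses.

    DFT (zero-padded) of the difference/average sequences; the LS problem
    over stacked real/imag parts of all bins is solved through its normal
    equations.  Because the padded DFT columns are orthogonal the solution
    equals the time-domain LS solution exactly, so the known-noise
    errors-in-variables correction (subtracting n * sigma^2 / 2 from both
    diagonal Gram entries; the lhs/regressor noise cross-terms cancel for
    the difference/average pair) can be applied on the same scale.

    Returns (kpl, r, rss) arrays over the batch.
    """
    n = dL.shape[-1]
    m = zero_pad * n
    Yl = np.fft.fft(dL, n=m, axis=-1)
    Yp = np.fft.fft(Pa, n=m, axis=-1)
    Ya = np.fft.fft(La, n=m, axis=-1)

    # Gram entries of the stacked real/imag design, scaled back by 1/m so
    # they match the time-domain inner products (Parseval).
    def dot(a, b):
        return (a.conj() * b).sum(axis=-1).real / m

    g_pp = dot(Yp, Yp)
    g_pl = dot(Yp, Ya)
    g_ll = dot(Ya, Ya)
    b_p = dot(Yp, Yl)
    b_l = dot(Ya, Yl)
    y_y = dot(Yl, Yl)

    # errors-in-variables correction c*I, capped so the corrected Gram keeps
    # at least 20% of the raw smallest eigenvalue (the correction shifts
    # both eigenvalues down by exactly lam*c); an uncapped correction can
    # push the matrix towards singularity at low lactate signal and the
    # resulting heavy-tailed estimates shift even the median.
    corr = n * noise_sd**2 / 2.0
    tr0 = g_pp + g_ll
    eigmin0 = tr0 / 2.0 - np.sqrt(((g_pp - g_ll) / 2.0) ** 2 + g_pl**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(corr > 0,
                       np.clip(0.8 * eigmin0 / max(corr, 1e-300), 0.0, 1.0),
                       0.0)
    a11 = g_pp - lam * corr
    a22 = g_ll - lam * corr
    a12 = -g_pl
    det = a11 * a22 - a12 * a12

    # design X = [Pa, -La], beta = (kpl, r): X^T y = (b_p, -b_l)
    with np.errstate(divide="ignore", invalid="ignore"):
        kpl = (a22 * b_p + a12 * b_l) / det
        r = (-a12 * b_p - a11 * b_l) / det
    # fall back to pseudo-inverse behaviour for degenerate systems
    bad = ~np.isfinite(kpl) | ~np.isfinite(r) | (np.abs(det) <= 0)
    if np.any(bad):
        kpl = np.atleast_1d(kpl)
        r = np.atleast_1d(r)
        A_flat = np.stack([np.broadcast_to(a11, kpl.shape),
                           np.broadcast_to(a12, kpl.shape),
                           np.broadcast_to(a22, kpl.shape)], axis=-1)
        bp = np.broadcast_to(np.atleast_1d(b_p), kpl.shape)
        bl = np.broadcast_to(np.atleast_1d(b_l), kpl.shape)
        for i in np.flatnonzero(np.atleast_1d(bad)):
            M = np.array([[A_flat[i, 0], A_flat[i, 1]],
                          [A_flat[i, 1], A_flat[i, 2]]])
            rhs = np.array([bp[i], -bl[i]])
            sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
            kpl[i], r[i] = sol[0], sol[1]
        kpl = kpl.reshape(np.shape(det))
        r = r.reshape(np.shape(det))

    rss = y_y - 2 * kpl * b_p + 2 * r * b_l + kpl**2 * g_pp \
        + r**2 * g_ll - 2 * kpl * r * g_pl
    rss = np.maximum(rss, 0.0)
    return kpl, r, rss


def _solve_freq_domain_fixed_r(dL, Pa, La, dt, r, noise_sd, zero_pad=4):
    """One-parameter kPL solve with the relaxation rate fixed."""
    n = dL.shape[-1]
    m = zero_pad * n
    Yl = np.fft.fft(dL + r * La, n=m, axis=-1)
    Yp = np.fft.fft(Pa, n=m, axis=-1)

    def dot(a, b):
        return (a.conj() * b).sum(axis=-1).real / m

    g_pp = dot(Yp, Yp)
    corr = np.minimum(n * noise_sd**2 / 2.0, 0.8 * g_pp)  # same PD cap
    den = g_pp - corr
    num = dot(Yp, Yl)
    with np.errstate(divide="ignore", invalid="ignore"):
        kpl = np.where(np.abs(den) > 0, num / den, 0.0)
    rss = np.maximum(dot(Yl, Yl) - 2 * kpl * num + kpl**2 * dot(Yp, Yp), 0.0)
    return kpl, rss


def _validate_courses(pyr, lac):
    pyr = np.asarray(pyr, dtype=float)
    lac = np.asarray(lac, dtype=float)
    if pyr.shape != lac.shape:
        raise ValueError("pyruvate and lactate courses must have equal length")
    if pyr.shape[-1] < 4:
        raise ValueError("need at least 4 frames")
    if not (np.all(np.isfinite(pyr)) and np.all(np.isfinite(lac))):
        raise ValueError("courses must be finite")
    if not np.any(pyr != 0):
        raise ValueError("pyruvate course is identically zero: kPL unidentifiable")
    return pyr, lac


def fit_kpl_frequency_domain(
    pyr_course: np.ndarray,
    lac_course: np.ndarray,
    frame_spacing: float,
    noise_sd: float = 0.0,
    inv_t1_eff_fixed: float | None = None,
) -> KineticFitResult:
    """Frequency-domain linear least-squares estimate of (kPL, 1/T1eff).

    ``noise_sd`` is the per-sample SD of zero-mean noise on the courses
    (e.g. from :meth:`NoiseEstimate.component_sd`); when positive, the
    consistent errors-in-variables Gram correction is applied.  With
    ``inv_t1_eff_fixed`` the relaxation rate is held and only kPL solved —
    used by the two-stage map fit where r comes from a high-SNR ROI course.
    """
    pyr, lac = _validate_courses(pyr_course, lac_course)
    dL, Pa, La = _difference_system(pyr, lac, frame_spacing)
    flags: list[str] = []
    if not np.any(lac != 0):
        flags.append(FLAG_ZERO_LACTATE)
    if inv_t1_eff_fixed is None:
        kpl, r, rss = _solve_freq_domain(dL, Pa, La, frame_spacing, noise_sd)
    else:
        kpl, rss = _solve_freq_domain_fixed_r(
            dL, Pa, La, frame_spacing, inv_t1_eff_fixed, noise_sd)
        r = np.asarray(inv_t1_eff_fixed, dtype=float)
    kpl = float(kpl)
    r = float(r)
    if kpl < 0:
        flags.append(FLAG_NEGATIVE_KPL)
    if r < 0:
        flags.append(FLAG_NEGATIVE_RATE)
    return KineticFitResult(
        k_pl_hat=kpl, inv_t1_eff_hat=r,
        residual_norm=float(math.sqrt(rss)),
        n_frames_used=pyr.shape[-1],
        method="frequency_domain",
        flags=tuple(flags),
    )


def _lactate_model(kpl: float, r: float, pyr: np.ndarray, times: np.ndarray,
                   lac0: float) -> np.ndarray:
    """Exact lactate solution for piecewise-linear pyruvate input.

    L(t_{k+1}) = L(t_k) e^{-r h} + kPL * int_0^h P(t_k + u) e^{-r (h-u)} du,
    with P linear on each interval; the initial condition is the observed
    first-frame lactate.
    """
    n = pyr.size
    out = np.empty(n)
    out[0] = lac0
    for k in range(n - 1):
        h = times[k + 1] - times[k]
        e = math.exp(-r * h)
        slope = (pyr[k + 1] - pyr[k]) / h
        if r > 1e-12:
            integral = pyr[k] * (1 - e) / r + slope * (h - (1 - e) / r) / r
        else:
            integral = pyr[k] * h + slope * h * h / 2.0
        out[k + 1] = out[k] * e + kpl * integral
    return out


_ORACLE_STARTS = ((0.005, 1 / 30.0), (0.02, 1 / 15.0),
                  (0.001, 1 / 60.0), (0.05, 0.5))


def fit_kpl_time_domain_oracle(
    pyr_course: np.ndarray,
    lac_course: np.ndarray,
    frame_spacing: float,
    bounds: tuple = ((0.0, 1 / 120.0), (0.1, 1.0)),
) -> KineticFitResult:
    """Bounded nonlinear time-domain fit — verification oracle.

    Fits the explicit exponential-convolution solution of the lactate
    balance (piecewise-linear pyruvate interpolation, first-frame lactate
    as the initial condition) by least squares with multi-start to avoid
    local minima.  Bounds: kPL in [0, 0.1] 1/s, 1/T1eff in [1/120, 1] 1/s.
    """
    pyr, lac = _validate_courses(pyr_course, lac_course)
    times = frame_spacing * np.arange(pyr.size)
    if not np.any(lac != 0):
        # no lactate response: kPL is exactly 0 and the relaxation rate is
        # unidentifiable (reported as the geometric mean of its bounds)
        return KineticFitResult(
            k_pl_hat=0.0,
            inv_t1_eff_hat=float(math.sqrt(bounds[0][1] * bounds[1][1])),
            residual_norm=0.0, n_frames_used=pyr.size,
            method="time_domain_oracle", flags=(FLAG_ZERO_LACTATE,),
        )
    lac0 = float(lac[0])

    def resid(x):
        return _lactate_model(x[0], x[1], pyr, times, lac0) - lac

    best = None
    for x0 in _ORACLE_STARTS:
        x0 = (min(max(x0[0], bounds[0][0]), bounds[1][0]),
              min(max(x0[1], bounds[0][1]), bounds[1][1]))
        try:
            sol = least_squares(resid, x0, bounds=bounds, xtol=1e-12, ftol=1e-12)
        except Exception as exc:  # pragma: no cover - optimizer failure path
            logger.debug("oracle start %s failed: %s", x0, exc)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.status <= 0:
        raise RuntimeError("time-domain oracle failed to converge from all starts")
    kpl, r = float(best.x[0]), float(best.x[1])
    flags = []
    if not np.any(lac != 0):
        flags.append(FLAG_ZERO_LACTATE)
    return KineticFitResult(
        k_pl_hat=kpl, inv_t1_eff_hat=r,
        residual_norm=float(np.linalg.norm(best.fun)),
        n_frames_used=pyr.size,
        method="time_domain_oracle",
        flags=tuple(flags),
    )


def lac_pyr_ratio(maps: MetaboliteMaps, roi_mask: np.ndarray) -> float:
    """Summed lactate over summed pyruvate within an ROI (time-summed maps)."""
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI")
    pyr = float(maps.pyruvate[mask].sum())
    if pyr <= 0:
        raise ValueError("zero pyruvate signal in ROI")
    return float(maps.lactate[mask].sum()) / pyr


def phase_corrected_real(combined_voxel_courses: np.ndarray) -> np.ndarray:
    """Project complex metabolite courses onto their shared signal phase.

    For coil-combined data both metabolites of a voxel share one constant
    phase (set by the coil sensitivities), so the reference phase is taken
    from the complex sum over *both* metabolites and all frames — which the
    high-SNR pyruvate dominates — and applied to each course.  The real
    part then carries the signal with zero-mean Gaussian noise, which the
    linear estimator assumes; estimating the phase per metabolite instead
    would align the lactate noise with itself and re-introduce a
    Rician-like positive bias at low SNR.

    Input shape (..., 2, n_frames), complex.
    """
    s = combined_voxel_courses.sum(axis=(-2, -1), keepdims=True)
    phase = np.where(np.abs(s) > 0, s / np.abs(s), 1.0)
    return (combined_voxel_courses * phase.conj()).real


@dataclass
class KplMapResult:
    """Voxel-wise kinetic fit over a mask; NaN marks unfitted voxels."""

    k_pl: np.ndarray
    inv_t1_eff: np.ndarray
    residual_norm: np.ndarray
    mask: np.ndarray
    n_failed: int = 0


def fit_kpl_map(
    combined: np.ndarray,
    mask: np.ndarray,
    frame_spacing: float,
    noise_sd: float = 0.0,
    inv_t1_eff_fixed: float | None = None,
    mode: str = "real",
) -> KplMapResult:
    """Apply the frequency-domain estimator to every masked voxel.

    ``combined`` is the coil-combined complex image (2, F, S, Y, X).  By
    default voxel courses are the phase-corrected real channel; with
    ``mode="magnitude"`` plain magnitudes are fitted instead (subject to
    Rician noise-floor bias at low SNR).  Unmasked voxels carry NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != combined.shape[2:]:
        raise ValueError("mask grid does not match image grid")
    shape = mask.shape
    nan = np.full(shape, np.nan)
    result = KplMapResult(k_pl=nan.copy(), inv_t1_eff=nan.copy(),
                          residual_norm=nan.copy(), mask=mask)
    idx = np.argwhere(mask)
    if idx.size == 0:
        logger.warning("fit_kpl_map: empty mask, returning all-missing map")
        return result

    courses = combined[:, :, mask.nonzero()[0], mask.nonzero()[1], mask.nonzero()[2]]
    courses = np.moveaxis(courses, -1, 0)        # (V, 2, F)
    if mode == "real":
        vals = phase_corrected_real(courses)
    elif mode == "magnitude":
        vals = np.abs(courses)
    else:
        raise ValueError("mode must be 'real' or 'magnitude'")
    pyr = vals[:, 0, :]
    lac = vals[:, 1, :]

    ok = np.any(pyr != 0, axis=-1)
    dL, Pa, La = _difference_system(pyr, lac, frame_spacing)
    if inv_t1_eff_fixed is None:
        kpl, r, rss = _solve_freq_domain(dL, Pa, La, frame_spacing, noise_sd)
    else:
        kpl, rss = _solve_freq_domain_fixed_r(
            dL, Pa, La, frame_spacing, inv_t1_eff_fixed, noise_sd)
        r = np.full_like(kpl, inv_t1_eff_fixed)

    good = ok & np.isfinite(kpl) & np.isfinite(r)
    n_failed = int(np.count_nonzero(~good))
    if n_failed:
        logger.warning("fit_kpl_map: %d voxel fits failed", n_failed)
    sel = idx[good]
    result.k_pl[tuple(sel.T)] = kpl[good]
    result.inv_t1_eff[tuple(sel.T)] = r[good]
    result.residual_norm[tuple(sel.T)] = np.sqrt(rss[good])
    result.n_failed = n_failed
    return result
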