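"""DSC-MRI perfusion quantification.

The T2*-weighted signal drop during a gadolinium bolus is converted to the
change in transverse relaxation rate

    dR2*(t) = -ln(S(t) / S0) / TE        [ms^-1]

with S0 the mean pre-bolus baseline signal.  Each voxel's first-pass curve is
then fitted with a gamma-variate bolus model

    c(t) = K * (t - t0)^alpha * exp(-(t - t0) / beta)   for t > t0

to exclude recirculation, and the cerebral blood volume (CBV) is the area
under the fitted curve, available in closed form as

    AUC = K * beta^(alpha+1) * Gamma(alpha+1).

rCBV maps are CBV divided by the mean CBV of the normal-appearing
contralateral side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize
from scipy.special import gammaln

from .imaging_io import BinaryMask, DynamicSeries, VolumeImage

__all__ = [
    "ConcentrationSeries",
    "GammaVariateFit",
    "signal_to_deltaR2star",
    "gamma_variate",
    "gamma_variate_auc",
    "fit_gamma_variate",
    "compute_cbv",
    "normalize_rcbv",
    "contralateral_reference_mask",
]

log = logging.getLogger(__name__)


@dataclass
class ConcentrationSeries:
    """Per-voxel dR2*(t) curves (ms^-1) with acquisition times in s."""

    curves: np.ndarray  # (T, x, y, z)
    time_s: np.ndarray
    baseline_frames: np.ndarray  # indices used for S0
    valid: np.ndarray  # 3D bool: voxels with usable S0 inside brain
    spacing: tuple[float, float, float]
    orientation: tuple[str, str, str]
    affine: np.ndarray

    def spatial_reference(self) -> VolumeImage:
        return VolumeImage(
            voxels=self.curves[0], spacing=self.spacing,
            orientation=self.orientation, affine=self.affine,
        )


@dataclass
class GammaVariateFit:
    """Fitted bolus parameters and the area under the fitted curve.

    ``auc`` always equals the closed form K*beta^(alpha+1)*Gamma(alpha+1) of
    the fitted parameters; ``success=False`` flags non-convergent or
    sub-noise-floor curves (auc 0 for flat curves).
    """

    K: float
    t0: float
    alpha: float
    beta: float
    auc: float
    rmse: float
    success: bool
    message: str = ""


def gamma_variate(t: np.ndarray, K: float, t0: float,
                  alpha: float, beta: float) -> np.ndarray:
    """K*(t-t0)^alpha*exp(-(t-t0)/beta) for t > t0, 0 before."""
    t = np.asarray(t, dtype=float)
    dt = t - t0
    out = np.zeros_like(dt)
    pos = dt > 0
    out[pos] = K * dt[pos] ** alpha * np.exp(-dt[pos] / beta)
    return out


def gamma_variate_auc(K: float, alpha: float, beta: float) -> float:
    """Closed-form integral of the gamma-variate over (t0, inf)."""
    return float(K * np.exp((alpha + 1) * np.log(beta) + gammaln(alpha + 1)))


def baseline_frame_indices(series: DynamicSeries, min_frames: int = 3) -> np.ndarray:
    """Frames fully acquired before the injection delay, minus the first.

    The first frame is discarded as a steady-state transient; at least
    ``min_frames`` baseline frames are required.
    """
    t = series.time_s
    pre = np.nonzero(t + series.tr_s <= series.injection_delay_s + 1e-9)[0]
    pre = pre[pre > 0]
    if len(pre) == 0:
        pre = np.array([0])
    if len(pre) < min_frames:
        raise ValueError(
            f"only {len(pre)} baseline frames before the "
            f"{series.injection_delay_s} s injection delay; need {min_frames}"
        )
    return pre


def signal_to_deltaR2star(series: DynamicSeries,
                          brain: BinaryMask | None = None,
                          min_baseline_frames: int = 3) -> ConcentrationSeries:
    """Convert a DSC signal series to dR2*(t) = -ln(S/S0)/TE in ms^-1.

    S0 is the per-voxel mean over the baseline frames.  Voxels outside the
    brain mask or with S0 <= 0 are flagged invalid and set to 0.
    """
    if brain is not None:
        brain.check_geometry(series.spatial_reference())
    base = baseline_frame_indices(series, min_baseline_frames)
    s0 = series.frames[base].mean(axis=0)
    valid = s0 > 0
    if brain is not None:
        valid &= brain.voxels
    curves = np.zeros_like(series.frames)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = series.frames / s0[None, ...]
        ratio = np.where(ratio > 0, ratio, np.nan)
        conv = -np.log(ratio) / series.te_ms
    conv = np.nan_to_num(conv, nan=0.0, posinf=0.0, neginf=0.0)
    curves[:, valid] = conv[:, valid]
    return ConcentrationSeries(
        curves=curves,
        time_s=series.time_s,
        baseline_frames=base,
        valid=valid,
        spacing=series.spacing,
        orientation=series.orientation,
        affine=series.affine,
    )


def _fit_window(curve: np.ndarray, time: np.ndarray,
                arrival_frac: float = 0.1,
                tail_frac: float = 0.2) -> tuple[np.ndarray, int]:
    """First-pass window: from just before bolus arrival (first sample above
    ``arrival_frac`` of peak) to the first post-peak sample below
    ``tail_frac`` of peak, excluding recirculation."""
    ipk = int(np.argmax(curve))
    peak = curve[ipk]
    above = np.nonzero(curve[: ipk + 1] >= arrival_frac * peak)[0]
    start = int(above[0]) if len(above) else 0
    start = max(start - 1, 0)
    end = len(curve)
    for j in range(ipk + 1, len(curve)):
        if curve[j] < tail_frac * peak:
            end = j + 1
            break
    return np.arange(start, end), ipk


def _loglinear_init(curve, time, ipk, arrival_frac=0.1):
    """Initial (K, t0, alpha, beta) by log-linearising ln c = ln K +
    alpha*ln(t-t0) - (t-t0)/beta on the rising edge through the peak."""
    peak = curve[ipk]
    above = np.nonzero(curve[: ipk + 1] >= arrival_frac * peak)[0]
    i0 = int(above[0]) if len(above) else ipk
    dt_samp = time[1] - time[0] if len(time) > 1 else 1.0
    t0 = time[i0] - dt_samp if i0 > 0 else time[0] - dt_samp
    sel = np.nonzero((time > t0) & (curve > 0))[0]
    sel = sel[sel <= min(ipk + 3, len(curve) - 1)]
    if len(sel) >= 3:
        x1 = np.log(time[sel] - t0)
        x2 = time[sel] - t0
        A = np.column_stack([np.ones_like(x1), x1, x2])
        coef, *_ = np.linalg.lstsq(A, np.log(curve[sel]), rcond=None)
        K = float(np.exp(coef[0]))
        alpha = float(coef[1])
        beta = float(-1.0 / coef[2]) if coef[2] < 0 else 2.0
    else:
        K, alpha, beta = peak, 2.0, 2.0
    alpha = float(np.clip(alpha, 0.1, 20.0))
    beta = float(np.clip(beta, 0.1, 60.0))
    K = max(K, 1e-12)
    return K, t0, alpha, beta


def fit_gamma_variate(curve: np.ndarray, time_s: np.ndarray,
                      noise_floor: float = 0.0,
                      max_restarts: int = 3,
                      rng: np.random.Generator | None = None) -> GammaVariateFit:
    """Nonlinear least-squares fit of the gamma-variate to one dR2* curve.

    Fits only the first pass (window from bolus arrival to the first
    post-peak sample below 20% of peak) to avoid recirculation.  Parameters
    are fit in log space for K/alpha/beta positivity; up to ``max_restarts``
    jittered restarts.  A curve whose peak does not exceed ``noise_floor``
    (or that is all zero) returns a failure flag with auc 0.
    """
    curve = np.asarray(curve, dtype=float)
    time = np.asarray(time_s, dtype=float)
    peak = float(curve.max(initial=0.0))
    if peak <= 0 or peak <= noise_floor:
        return GammaVariateFit(0.0, 0.0, 0.0, 0.0, auc=0.0, rmse=0.0,
                               success=False, message="below noise floor")
    win, ipk = _fit_window(curve, time)
    if len(win) < 6:
        win = np.arange(max(win[0] - (6 - len(win)), 0), win[-1] + 1)
    if len(win) < 5:
        return GammaVariateFit(0.0, 0.0, 0.0, 0.0, auc=0.0, rmse=0.0,
                               success=False, message="too few samples")
    tw, cw = time[win], curve[win]
    K0, t00, a0, b0 = _loglinear_init(curve, time, ipk)
    rng = rng or np.random.default_rng(0)

    def resid(p):
        K, t0, alpha, beta = np.exp(p[0]), p[1], np.exp(p[2]), np.exp(p[3])
        return gamma_variate(tw, K, t0, alpha, beta) - cw

    t0_hi = time[ipk] - 1e-6
    best = None
    p0 = np.array([np.log(K0), t00, np.log(a0), np.log(b0)])
    for attempt in range(max_restarts + 1):
        p_init = p0.copy()
        if attempt > 0:
            p_init += rng.normal(0, 0.3, size=4)
            p_init[1] = min(p_init[1], t0_hi - 0.5)
        try:
            sol = optimize.least_squares(
                resid, p_init,
                bounds=([-np.inf, -np.inf, np.log(1e-2), np.log(1e-2)],
                        [np.inf, t0_hi, np.log(50.0), np.log(120.0)]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:  # pragma: no cover - scipy internal failures
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.cost <= (1e-8 * max(peak, 1e-12)) ** 2 * len(tw):
            break
    if best is None:
        return GammaVariateFit(0.0, 0.0, 0.0, 0.0, auc=0.0, rmse=0.0,
                               success=False, message="no convergence")
    K, t0, alpha, beta = (float(np.exp(best.x[0])), float(best.x[1]),
                          float(np.exp(best.x[2])), float(np.exp(best.x[3])))
    rmse = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return GammaVariateFit(
        K=K, t0=t0, alpha=alpha, beta=beta,
        auc=gamma_variate_auc(K, alpha, beta),
        rmse=rmse, success=True,
    )


def integrate_fit_numeric(fit: GammaVariateFit, n: int = 20000,
                          t_max_factor: float = 40.0) -> float:
    """Trapezoidal integral of the fitted curve on a fine grid (cross-check
    for the closed-form auc)."""
    if not fit.success or fit.K == 0:
        return 0.0
    t_max = fit.t0 + t_max_factor * fit.beta * max(fit.alpha, 1.0)
    t = np.linspace(fit.t0, t_max, n)
    return float(integrate.trapezoid(
        gamma_variate(t, fit.K, fit.t0, fit.alpha, fit.beta), t))


def compute_cbv(conc: ConcentrationSeries,
                noise_floor: float = 0.0,
                integration: str = "closed_form") -> tuple[VolumeImage, dict]:
    """Per-voxel CBV map: area under the gamma-variate fit of each curve.

    Identical curves (common in noise-free phantoms) are fitted once.  Failed
    fits produce CBV 0 and are counted in the returned QC dict, never NaN.
    ``integration`` selects the closed form (default) or numerical
    integration of the fitted curve; the two agree to fine tolerance.
    """
    if integration not in ("closed_form", "numeric"):
        raise ValueError(f"unknown integration {integration!r}")
    shape = conc.curves.shape[1:]
    cbv = np.zeros(shape)
    idx = np.transpose(np.nonzero(conc.valid))
    cache: dict[bytes, tuple[float, bool, float]] = {}
    n_failed = 0
    rmses = []
    for i, j, k in idx:
        curve = np.ascontiguousarray(conc.curves[:, i, j, k])
        key = curve.tobytes()
        if key not in cache:
            fit = fit_gamma_variate(curve, conc.time_s, noise_floor=noise_floor)
            auc = fit.auc if integration == "closed_form" \
                else integrate_fit_numeric(fit)
            cache[key] = (auc, fit.success, fit.rmse)
        auc, ok, rmse = cache[key]
        cbv[i, j, k] = auc
        if ok:
            rmses.append(rmse)
        elif curve.max(initial=0.0) > 0:
            n_failed += 1
    qc = {
        "n_voxels_fit": int(len(idx)),
        "n_failed": int(n_failed),
        "median_rmse": float(np.median(rmses)) if rmses else 0.0,
    }
    if n_failed:
        log.info("compute_cbv: %d voxels failed to fit (set to 0)", n_failed)
    vol = VolumeImage(
        voxels=cbv, spacing=conc.spacing, orientation=conc.orientation,
        units="CBV a.u.", affine=conc.affine,
    )
    return vol, qc


def normalize_rcbv(cbv: VolumeImage, contralateral: BinaryMask) -> VolumeImage:
    """rCBV = CBV / mean(CBV over the normal-appearing contralateral mask)."""
    cbv.check_geometry(contralateral)
    if contralateral.count == 0:
        raise ValueError("contralateral mask is empty")
    mean = float(cbv.voxels[contralateral.voxels].mean())
    if mean <= 0:
        raise ValueError(f"non-positive contralateral mean CBV ({mean})")
    return cbv.with_voxels(cbv.voxels / mean, units="rCBV ratio")


def contralateral_reference_mask(brain: BinaryMask,
                                 tumor_hemisphere: BinaryMask,
                                 flair: BinaryMask | None = None) -> BinaryMask:
    """Normal-appearing contralateral ROI for rCBV normalization.

    The tumor-bearing hemisphere is mirrored onto the healthy side; any
    mirrored FLAIR hypersignal is excluded so edema never contaminates the
    reference.
    """
    from .imaging_io import mask_ops, mirror_mask

    contra = mask_ops(brain, mirror_mask(tumor_hemisphere), "AND")
    if flair is not None:
        contra = mask_ops(contra, mirror_mask(flair), "NOT")
    return contra
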