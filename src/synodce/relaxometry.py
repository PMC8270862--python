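"""Spoiled gradient-echo (SPGR) relaxometry.

The dynamic and variable-flip-angle (VFA) acquisitions are 3D SPGR
sequences, whose steady-state signal is

    S = M0 * sin(alpha) * (1 - E1) / (1 - E1 * cos(alpha)),   E1 = exp(-TR/T1)

with flip angle ``alpha``, repetition time ``TR`` and longitudinal
relaxation time ``T1``.  This module provides the forward signal model,
native-T1 estimation from VFA images, and the conversion of a dynamic
signal time course to gadolinium concentration via the fast-water-exchange
(linear) relation R1(t) = R10 + r1 * C(t).

All times in this module are in **seconds**; conversion to minutes happens
only at the pharmacokinetics boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_RELAXIVITY",
    "SPGRParams",
    "T1MapResult",
    "ConcentrationResult",
    "spgr_signal",
    "fit_vfa_t1",
    "signal_to_concentration",
    "concentration_to_signal",
]

#: Longitudinal relaxivity of gadoterate at 3 T, L·mmol⁻¹·s⁻¹.
DEFAULT_RELAXIVITY = 3.5


@dataclass(frozen=True)
class SPGRParams:
    """Parameters of the SPGR steady-state signal equation.

    Attributes
    ----------
    m0 : equilibrium magnetisation (arbitrary signal units)
    t1 : longitudinal relaxation time, seconds
    flip_angle : degrees, in (0, 90]
    tr : repetition time, seconds
    """

    m0: float
    t1: float
    flip_angle: float
    tr: float

    def __post_init__(self) -> None:
        if not self.t1 > 0:
            raise ValueError(f"t1 must be > 0, got {self.t1}")
        if not self.tr > 0:
            raise ValueError(f"tr must be > 0, got {self.tr}")
        if not 0 < self.flip_angle <= 90:
            raise ValueError(f"flip_angle must be in (0, 90], got {self.flip_angle}")


@dataclass
class T1MapResult:
    """Voxelwise native-T1 fit.

    ``t1`` (seconds) and ``m0`` are valid only where ``fit_ok`` is True;
    degenerate voxels (zero signal, non-physical slope) carry NaN.
    """

    t1: np.ndarray
    m0: np.ndarray
    fit_ok: np.ndarray


@dataclass
class ConcentrationResult:
    """Concentration time series with per-timepoint validity.

    ``conc`` is in mmol/L; entries where the measured signal implies an
    E1 outside (0, 1) are NaN and flagged ``valid=False`` rather than
    being clipped.
    """

    conc: np.ndarray
    valid: np.ndarray


def spgr_signal(p: SPGRParams | None = None, *, m0=None, t1=None,
                flip_angle=None, tr=None) -> np.ndarray:
    """SPGR steady-state signal; scalar or voxelwise (broadcasting) form.

    Either pass an :class:`SPGRParams` or the keyword arrays directly.
    """
    if p is not None:
        m0, t1, flip_angle, tr = p.m0, p.t1, p.flip_angle, p.tr
    m0 = np.asarray(m0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    alpha = np.deg2rad(np.asarray(flip_angle, dtype=float))
    e1 = np.exp(-np.asarray(tr, dtype=float) / t1)
    return m0 * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))


def fit_vfa_t1(signals: np.ndarray, flip_angles, tr: float,
               nonlinear_refine: bool = False) -> T1MapResult:
    """Estimate native T1 and M0 from variable-flip-angle SPGR images.

    Uses the standard linearisation (DESPOT1): plotting y = S/sin(a)
    against x = S/tan(a) gives a line with slope E1 = exp(-TR/T1) and
    intercept M0 (1 - E1).  Voxels where the fitted slope falls outside
    (0, 1) or all signals vanish are flagged ``fit_ok=False``.

    Parameters
    ----------
    signals : array, shape (n_angles, ...) — one image per flip angle.
    flip_angles : degrees, length n_angles, at least two distinct.
    tr : repetition time, seconds.
    nonlinear_refine : if True, refine each valid voxel with bounded
        nonlinear least squares on the signal equation (slower; identical
        on noiseless data).
    """
    signals = np.asarray(signals, dtype=float)
    fa = np.asarray(flip_angles, dtype=float)
    if fa.ndim != 1 or signals.shape[0] != fa.size:
        raise ValueError("signals first axis must index flip angles")
    if np.unique(fa).size < 2:
        raise ValueError("need at least 2 distinct flip angles")
    if tr <= 0:
        raise ValueError("tr must be > 0")

    a = np.deg2rad(fa).reshape((-1,) + (1,) * (signals.ndim - 1))
    y = signals / np.sin(a)
    x = signals / np.tan(a)

    n = fa.size
    sx = x.sum(axis=0)
    sy = y.sum(axis=0)
    sxx = (x * x).sum(axis=0)
    sxy = (x * y).sum(axis=0)
    denom = n * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n

    ok = np.isfinite(slope) & (slope > 0) & (slope < 1) & (signals > 0).any(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(ok, -tr / np.log(np.where(ok, slope, 0.5)), np.nan)
        m0 = np.where(ok, intercept / (1.0 - np.where(ok, slope, 0.5)), np.nan)
    ok = ok & np.isfinite(t1) & (t1 > 0) & np.isfinite(m0) & (m0 > 0)
    t1 = np.where(ok, t1, np.nan)
    m0 = np.where(ok, m0, np.nan)

    if nonlinear_refine:
        from scipy.optimize import least_squares

        flat_ok = np.flatnonzero(ok.ravel())
        t1f, m0f = t1.ravel(), m0.ravel()
        sig_flat = signals.reshape(n, -1)
        for idx in flat_ok:
            obs = sig_flat[:, idx]

            def resid(p):
                return spgr_signal(m0=p[0], t1=p[1], flip_angle=fa, tr=tr) - obs

            sol = least_squares(resid, x0=[m0f[idx], t1f[idx]],
                                bounds=([0, 1e-6], [np.inf, 20.0]))
            m0f[idx], t1f[idx] = sol.x
        t1 = t1f.reshape(t1.shape)
        m0 = m0f.reshape(m0.shape)

    return T1MapResult(t1=t1, m0=m0, fit_ok=ok)


def concentration_to_signal(conc: np.ndarray, t10, m0, tr: float,
                            flip_angle: float,
                            r1: float = DEFAULT_RELAXIVITY) -> np.ndarray:
    """Forward map: gadolinium concentration (mmol/L) to SPGR signal.

    R1(t) = 1/t10 + r1*C(t); broadcasting over leading axes.
    """
    conc = np.asarray(conc, dtype=float)
    r1_t = 1.0 / np.asarray(t10, dtype=float) + r1 * conc
    return spgr_signal(m0=m0, t1=1.0 / r1_t, flip_angle=flip_angle, tr=tr)


def signal_to_concentration(dynamic_signal: np.ndarray, baseline_frames: int,
                            t10, tr: float, flip_angle: float,
                            r1: float = DEFAULT_RELAXIVITY) -> ConcentrationResult:
    """Convert a dynamic SPGR signal time course to concentration.

    The equilibrium magnetisation is eliminated using the mean of the
    pre-bolus baseline frames together with the native T1: solving the
    SPGR equation for M0 at the baseline signal and T1 = t10, then
    inverting it per timepoint for E1(t), R1(t) = -ln E1 / TR and

        C(t) = (R1(t) - 1/t10) / r1        [mmol/L]

    Time axis is the **last** axis; leading axes are voxels.  Timepoints
    whose signal implies E1 outside (0, 1) are NaN with ``valid=False``.
    """
    s = np.asarray(dynamic_signal, dtype=float)
    if baseline_frames < 1:
        raise ValueError("baseline_frames must be >= 1")
    if s.shape[-1] <= baseline_frames:
        raise ValueError("series shorter than baseline_frames")
    t10 = np.asarray(t10, dtype=float)
    if np.any(t10 <= 0):
        raise ValueError("t10 must be > 0")

    alpha = np.deg2rad(flip_angle)
    sin_a, cos_a = np.sin(alpha), np.cos(alpha)
    s0 = s[..., :baseline_frames].mean(axis=-1)

    e10 = np.exp(-tr / t10)
    # M0 sin(alpha) from the baseline signal
    m0sin = s0 * (1.0 - e10 * cos_a) / (1.0 - e10)

    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (m0sin[..., None] - s) / (m0sin[..., None] - s * cos_a)
    valid = np.isfinite(e1) & (e1 > 0) & (e1 < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1_t = -np.log(np.where(valid, e1, 0.5)) / tr
        conc = (r1_t - 1.0 / t10[..., None]) / r1
    conc = np.where(valid, conc, np.nan)
    return ConcentrationResult(conc=conc, valid=valid)
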