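"""Non-compartmental deconvolution of pulmonary exposure.

The NCA route to lung exposure treats pulmonary absorption as a single
first-order process: the mean absorption time is the difference of mean
residence times after inhalation and i.v. dosing,

    MAT = MRT_inh - MRT_iv,        k_a = 1 / MAT,

pulmonary bioavailability comes from the dose-normalised AUC ratio, and the
lung AUC follows from treating ``k_a`` as the elimination rate from a lung
of volume ``V_lung``:

    AUC(0-inf, lung) = Dose_inh * F_pul / (k_a * V_lung).

When the systemic disposition or absorption violates the single-process
assumption the MAT can come out negative, in which case no lung AUC can be
computed and the result is flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NCAProfileResult", "NCAResult", "nca_auc_aumc", "nca_deconvolve"]

DEFAULT_V_LUNG = 0.840  # L
DEFAULT_N_TERMINAL = 3


@dataclass(frozen=True)
class NCAProfileResult:
    """AUC/AUMC/MRT of a single profile with the terminal-slope estimate."""

    auc_0_inf: float
    aumc_0_inf: float
    mrt: float
    lambda_z: float
    auc_0_last: float
    valid: bool = True
    reason: str = ""


@dataclass(frozen=True)
class NCAResult:
    """Deconvolution outcome; ``valid`` is False when MAT <= 0 (or either
    profile failed), in which case k_a, F_pul-derived lung AUC are undefined."""

    mrt_iv: float | None
    mrt_inh: float | None
    mat: float | None
    k_a: float | None
    f_pul: float | None
    auc_lung: float | None
    auc_plasma_inh: float | None
    valid: bool
    reason: str = ""


def _lambda_z(times: np.ndarray, conc: np.ndarray, n_terminal: int,
              best_fit: bool) -> tuple[float, float, int]:
    """Terminal slope from log-linear regression on the last points.

    Returns (lambda_z, intercept at t=0 of the log-linear line, n_points).
    With ``best_fit`` the number of terminal points (>= 3) maximising the
    adjusted R^2 is chosen; otherwise the last ``n_terminal`` points are
    used.  A non-negative slope makes lambda_z non-estimable.
    """
    n = len(times)
    candidates = range(3, n + 1) if best_fit else [min(n_terminal, n)]
    best = None
    for k in candidates:
        if k < 2:
            continue
        t = times[-k:]
        y = np.log(conc[-k:])
        slope, intercept = np.polyfit(t, y, 1)
        if slope >= -1e-12:  # flat or rising terminal phase
            continue
        resid = y - (slope * t + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2) if k > 2 else r2
        if best is None or adj > best[0]:
            best = (adj, -slope, intercept, k)
    if best is None:
        raise ValueError("lambda_z non-estimable (terminal slope not negative)")
    return best[1], best[2], best[3]


def nca_auc_aumc(
    times: np.ndarray,
    conc: np.ndarray,
    n_terminal: int = DEFAULT_N_TERMINAL,
    best_fit_lambda_z: bool = False,
    linlog: bool = True,
) -> NCAProfileResult:
    """AUC(0-inf) and AUMC(0-inf) of one concentration-time profile.

    Trapezoids are linear on the rising limb and logarithmic on the
    descending limb (``linlog=True``, the usual 'linear-up/log-down' rule);
    the tail beyond the last observation is extrapolated from the terminal
    slope: ``C_last/lz`` for AUC and ``C_last*t_last/lz + C_last/lz^2`` for
    AUMC.  Leading zero concentrations (pre-absorption) contribute via
    linear trapezoids.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times.shape != conc.shape or times.size < 3:
        raise ValueError("need matched times/concentrations with >= 3 points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")

    pos = conc > 0
    if pos.sum() < 3:
        return NCAProfileResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                                valid=False, reason="fewer than 3 positive points")
    try:
        lz, _, _ = _lambda_z(times[pos], conc[pos], n_terminal, best_fit_lambda_z)
    except ValueError as exc:
        return NCAProfileResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                                valid=False, reason=str(exc))

    auc = 0.0
    aumc = 0.0
    for i in range(len(times) - 1):
        t0, t1 = times[i], times[i + 1]
        c0, c1 = conc[i], conc[i + 1]
        dt = t1 - t0
        if linlog and c1 < c0 and c1 > 0 and c0 > 0:
            # log trapezoid on the descending limb
            k = np.log(c0 / c1) / dt
            auc += (c0 - c1) / k
            aumc += (t0 * c0 - t1 * c1) / k + (c0 - c1) / k**2
        else:
            auc += 0.5 * (c0 + c1) * dt
            aumc += 0.5 * (t0 * c0 + t1 * c1) * dt

    t_last = times[pos][-1]
    c_last = conc[pos][-1]
    auc_last = auc
    auc += c_last / lz
    aumc += c_last * t_last / lz + c_last / lz**2
    mrt = aumc / auc
    return NCAProfileResult(auc, aumc, mrt, lz, auc_last)


def nca_deconvolve(
    iv_times: np.ndarray,
    iv_conc: np.ndarray,
    inh_times: np.ndarray,
    inh_conc: np.ndarray,
    dose_iv: float,
    dose_inh: float,
    v_lung: float = DEFAULT_V_LUNG,
    **nca_options,
) -> NCAResult:
    """MRT/MAT-based deconvolution of one subject's i.v. + inhalation data."""
    if dose_iv <= 0 or dose_inh <= 0:
        raise ValueError("doses must be positive")
    iv = nca_auc_aumc(iv_times, iv_conc, **nca_options)
    inh = nca_auc_aumc(inh_times, inh_conc, **nca_options)
    if not iv.valid or not inh.valid:
        which = "i.v." if not iv.valid else "inhalation"
        reason = iv.reason if not iv.valid else inh.reason
        return NCAResult(None, None, None, None, None, None, None,
                         valid=False, reason=f"{which} profile: {reason}")
    mat = inh.mrt - iv.mrt
    f_pul = (inh.auc_0_inf / dose_inh) / (iv.auc_0_inf / dose_iv)
    if mat <= 0:
        return NCAResult(iv.mrt, inh.mrt, mat, None, f_pul, None,
                         inh.auc_0_inf, valid=False, reason="negative MAT")
    k_a = 1.0 / mat
    auc_lung = dose_inh * f_pul / (k_a * v_lung)
    return NCAResult(iv.mrt, inh.mrt, mat, k_a, f_pul, auc_lung,
                     inh.auc_0_inf, valid=True)
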