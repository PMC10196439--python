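"""Noncompartmental analysis of concentration-time profiles.

Cmax/Tmax are read from the sampled points; AUC uses the linear-up/log-down
trapezoid; the terminal rate constant (lambda_z) comes from a log-linear
regression whose window (>= 3 points after Tmax) is selected by maximizing
the adjusted coefficient of determination.  Non-estimable terminal phases are
reported as missing (NaN), mirroring how clinical tables print "n/a".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import ConcentrationProfile


@dataclass
class PKMetrics:
    """Summary exposure metrics for one subject."""

    cmax: float  # ng/mL
    tmax: float  # h
    auc_0_t: float  # ng*h/mL up to the last quantifiable sample
    auc_0_inf: float  # ng*h/mL
    t_half: float  # h (NaN when lambda_z is not estimable)
    lambda_z: float  # 1/h
    fa: float = np.nan  # fraction absorbed, when the simulation provides it


def auc_lin_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    """Linear-up/log-down trapezoidal AUC."""
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    lin = (c1 + c2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        logseg = (c1 - c2) / np.log(c1 / c2)
    down = (c2 < c1) & (c2 > 0) & (c1 > 0)
    seg = np.where(down, np.where(np.isfinite(logseg), logseg, lin), lin)
    return float(np.sum(seg * dt))


def _lambda_z(t: np.ndarray, c: np.ndarray, i_tmax: int) -> tuple[float, float]:
    """Best terminal log-linear slope by adjusted-R2 window selection."""
    best = (np.nan, -np.inf)
    n = t.size
    for start in range(i_tmax + 1, n - 2):
        tt = t[start:]
        cc = c[start:]
        mask = cc > 0
        if mask.sum() < 3:
            continue
        tt, cc = tt[mask], cc[mask]
        k = tt.size
        slope, intercept = np.polyfit(tt, np.log(cc), 1)
        if slope >= 0:
            continue
        resid = np.log(cc) - (slope * tt + intercept)
        ss_res = float(resid @ resid)
        y = np.log(cc)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot <= 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        r2_adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if r2_adj > best[1] + 1e-12:
            best = (-slope, r2_adj)
    return best


def pk_metrics(
    profile: ConcentrationProfile | tuple[np.ndarray, np.ndarray],
    sampling_times: np.ndarray,
    fa: float = np.nan,
) -> PKMetrics:
    """Compute NCA metrics on a profile evaluated at the sampling schedule.

    ``profile`` is either an engine output or a ``(times, conc)`` pair; the
    concentrations are interpolated onto ``sampling_times``.
    """
    if isinstance(profile, ConcentrationProfile):
        t_src, c_src = profile.times, profile.plasma_conc
        if np.isnan(fa) and profile.dose_mg > 0:
            fa = profile.fa
    else:
        t_src, c_src = profile
    ts = np.asarray(sampling_times, dtype=float)
    cs = np.interp(ts, t_src, c_src)
    if not np.any(cs > 0):
        return PKMetrics(0.0, 0.0, 0.0, 0.0, np.nan, np.nan, fa)
    i_max = int(np.argmax(cs))
    cmax = float(cs[i_max])
    tmax = float(ts[i_max])
    auc_t = auc_lin_up_log_down(ts, cs)
    lz, _ = _lambda_z(ts, cs, i_max)
    if np.isnan(lz) or lz <= 0:
        return PKMetrics(cmax, tmax, auc_t, np.nan, np.nan, np.nan, fa)
    c_last = float(cs[cs > 0][-1])
    return PKMetrics(
        cmax=cmax,
        tmax=tmax,
        auc_0_t=auc_t,
        auc_0_inf=auc_t + c_last / lz,
        t_half=np.log(2.0) / lz,
        lambda_z=lz,
        fa=fa,
    )
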