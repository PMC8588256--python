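"""Drift and diffusivity of knots from position time series.

The knot position along the chain (central core index, converted to
contour nm) is sign-linearized over the force-flip protocol,
``dx(t_n) = sum_i sign(F_i) (x_{i+1} - x_i)``, so the sawtooth becomes a
monotone drift.  The drift speed is the slope of a zero-intercept least
squares line; the diffusivity comes from a one-parameter fit of the
ballistic MSD law ``MSD(t) = (f_ext D t / sigma)^2 + 2 D t`` (the drift
velocity of a pulled knot is v0 = F_ext D / eps0, so D is the only free
parameter).  Analytic effective-diffusivity references (tortuosity and the
propelled-chiral-particle formula) and the stereoselectivity ratio phi_D
round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .units import UnitSystem, DEFAULT_UNITS
from .channel import HelicalChannelSpec, helix_geometry


@dataclass
class DriftSeries:
    """Knot-position time series in physical units (s, nm)."""

    times_s: np.ndarray
    position_nm: np.ndarray
    force_signs: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times_s) == len(self.position_nm)
                == len(self.force_signs)):
            raise ValueError("series arrays must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    @classmethod
    def from_trajectory(cls, traj, units: UnitSystem = DEFAULT_UNITS,
                        bond_nm: float | None = None) -> "DriftSeries":
        """Build from a Trajectory's located knot cores (i_middle)."""
        ts, xs, ss = traj.knot_position_series()
        if bond_nm is None:
            bond_nm = units.convert(1.0, "length")
        return cls(units.convert(ts, "time") * 1e-9, xs * bond_nm, ss)


@dataclass
class TransportResult:
    v_drift: float            # um/s
    v_drift_se: float
    D: float                  # um^2/s
    D_se: float
    r_squared: float
    method: str
    n_points: int = 0

    def summary(self) -> str:
        return (f"v_drift = {self.v_drift:.1f} +- {self.v_drift_se:.1f} um/s; "
                f"D = {self.D:.2f} +- {self.D_se:.2f} um^2/s "
                f"(R^2 = {self.r_squared:.4f}, {self.method})")


def linearize_drift(series: DriftSeries,
                    max_jump_nm: float | None = None) -> np.ndarray:
    """Cumulative sign-linearized displacement dx(t) in nm.

    dx(t_n) = sum_{i<n} sign(F_i) (x_{i+1} - x_i); under steady drift this
    is monotone in expectation regardless of force flips.
    """
    x = series.position_nm
    if len(x) < 2:
        raise ValueError("need at least 2 frames")
    inc = np.diff(x)
    if max_jump_nm is not None and np.any(np.abs(inc) > max_jump_nm):
        raise ValueError("position jump exceeds the chain length: frame gap")
    s = series.force_signs[:-1]
    return np.concatenate([[0.0], np.cumsum(s * inc)])


def fit_drift_speed(times_s: np.ndarray, dx_nm: np.ndarray) -> tuple[float, float, float]:
    """Zero-intercept LSQ slope of dx(t): (v um/s, SE, R^2).

    Accepts concatenated replica series (just stack the arrays).
    """
    t = np.asarray(times_s, dtype=float)
    x = np.asarray(dx_nm, dtype=float) * 1e-3   # nm -> um
    if len(t) < 10:
        raise ValueError("need at least 10 frames for a drift fit")
    stt = float(t @ t)
    v = float(t @ x) / stt
    resid = x - v * t
    dof = max(len(t) - 1, 1)
    se = float(np.sqrt((resid @ resid) / dof / stt))
    ss_tot = float(((x - x.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return v, se, r2


def msd_from_linearized(times_s: np.ndarray, dx_nm: np.ndarray,
                        force_signs: np.ndarray,
                        n_lags: int = 60):
    """MSD(lag) of the linearized displacement, windows restarted at flips.

    Frames are split into runs of constant force sign; non-overlapping
    windows within each run contribute (dx(t0+lag) - dx(t0))^2, so flips
    do not contaminate the lag statistics.  Returns (lags_s, msd_um2).
    """
    t = np.asarray(times_s, dtype=float)
    x = np.asarray(dx_nm, dtype=float) * 1e-3
    s = np.asarray(force_signs, dtype=float)
    dt = np.median(np.diff(t))
    bounds = np.concatenate([[0], np.where(np.diff(s) != 0)[0] + 1, [len(t)]])
    max_lag = min(n_lags, max(int((np.diff(bounds)).max()) - 1, 1))
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        seg = x[b0:b1]
        m = len(seg)
        for lag in range(1, max_lag + 1):
            if lag >= m:
                break
            # non-overlapping windows
            starts = np.arange(0, m - lag, lag)
            d = seg[starts + lag] - seg[starts]
            sums[lag] += float(d @ d)
            counts[lag] += len(d)
    good = counts > 0
    good[0] = False
    lags = np.arange(max_lag + 1)[good] * dt
    msd = sums[good] / counts[good]
    return lags, msd


def fit_msd_ballistic(lags_s: np.ndarray, msd_um2: np.ndarray,
                      f_ext: float = 0.05,
                      units: UnitSystem = DEFAULT_UNITS) -> tuple[float, float]:
    """One-parameter fit of MSD(t) = (f_ext D t / sigma)^2 + 2 D t.

    D is returned in um^2/s with its fit SE.  f_ext is the reduced force
    (eps0/sigma); sigma enters in um.  For f_ext = 0 this degenerates to
    the ordinary 1-D diffusion law MSD = 2 D t.
    """
    sigma_um = units.convert(1.0, "length") * 1e-3

    def model(t, d):
        return (f_ext * d * t / sigma_um) ** 2 + 2.0 * d * t

    lags = np.asarray(lags_s, dtype=float)
    msd = np.asarray(msd_um2, dtype=float)
    if len(lags) < 3:
        raise ValueError("need at least 3 MSD points")
    d0 = max(msd[0] / (2 * lags[0]), 1e-6)
    popt, pcov = curve_fit(model, lags, msd, p0=[d0],
                           bounds=(0.0, np.inf), maxfev=10000)
    d_fit = float(popt[0])
    if d_fit <= 0:
        raise ValueError("negative-D optimum: fit failure")
    d_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else 0.0
    return d_fit, d_se


def analyze_transport(series_list: list[DriftSeries],
                      f_ext: float = 0.05,
                      units: UnitSystem = DEFAULT_UNITS,
                      n_lags: int = 60) -> TransportResult:
    """Pooled transport analysis over replica series.

    Drift from a concatenated zero-intercept fit; D from the ballistic MSD
    fit per replica, pooled as mean +- SE over replicas (single replica:
    fit SE).
    """
    all_t, all_x = [], []
    d_vals, d_ses = [], []
    for s in series_list:
        dx = linearize_drift(s)
        all_t.append(s.times_s - s.times_s[0])
        all_x.append(dx)
        lags, msd = msd_from_linearized(s.times_s, dx, s.force_signs, n_lags)
        d, dse = fit_msd_ballistic(lags, msd, f_ext=f_ext, units=units)
        d_vals.append(d)
        d_ses.append(dse)
    t_cat = np.concatenate(all_t)
    x_cat = np.concatenate(all_x)
    v, v_se, r2 = fit_drift_speed(t_cat, x_cat)
    if len(d_vals) > 1:
        d_mean = float(np.mean(d_vals))
        d_se = float(np.std(d_vals, ddof=1) / np.sqrt(len(d_vals)))
    else:
        d_mean, d_se = d_vals[0], d_ses[0]
    return TransportResult(v, v_se, d_mean, d_se, r2, "drift_fit+msd_ballistic",
                           n_points=len(t_cat))


# ---------------------------------------------------------------------------
# analytic references
# ---------------------------------------------------------------------------

def d_eff_tortuosity(d0: float, spec: HelicalChannelSpec) -> float:
    """Effective diffusivity D_eff = D0 / tortuosity of the channel."""
    return d0 / helix_geometry(spec)[3]


def d_eff_active_chiral(d: float, v0: float, spec: HelicalChannelSpec) -> float:
    """Propelled-chiral-particle effective diffusivity.

    D_eff = D + v0^2 D_theta / [2 (D_theta^2 + Omega^2)] with rotational
    diffusion D_theta = 3 D / (4 R_H^2) and channel-induced rotation rate
    Omega = v0 / (2 pi k sigma).  Requires R_H > 0.
    """
    if spec.r_h <= 0:
        raise ValueError("R_H = 0: rotational diffusion D_theta undefined")
    d_theta = 3.0 * d / (4.0 * spec.r_h ** 2)
    omega = v0 / (2.0 * np.pi * spec.pitch_k)
    return d + v0 ** 2 * d_theta / (2.0 * (d_theta ** 2 + omega ** 2))


def selectivity_ratio(d_equichiral: float, d_antichiral: float) -> float:
    """Stereoselectivity phi_D = D_= / D_+- (both must be positive).

    For circular chains the field reports the reciprocal D_+- / D_=; pass
    the arguments swapped and label accordingly.
    """
    if d_equichiral <= 0 or d_antichiral <= 0:
        raise ValueError("diffusivities must be positive")
    return d_equichiral / d_antichiral
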