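"""MSD statistics: ensemble averaging, log-log profiles, anomalous exponent.

The mean squared displacement of two-dimensional diffusion is modelled as

    <r^2>(t) = 4 D t^alpha

with anomalous exponent alpha (1: normal diffusion, 0 < alpha < 1:
subdiffusion, alpha ~ 0: confinement).  In log-log form

    log(<r^2>/t) = log(4 D) + (alpha - 1) log(t)

so the profile of log(<r^2>/t) against log(t) is flat for normal diffusion
and has slope alpha - 1 otherwise (natural logarithms throughout).

Time-dependent diffusivities of subdiffusion:

    D_app(t)  = D t^(1-alpha)          (apparent)
    D_inst(t) = alpha D t^(1-alpha)    (instantaneous)

The effective diffusion coefficient D_eff is D for normal diffusion and
D_app evaluated at the observation horizon (2 s by default) otherwise.
MSD is an ensemble quantity: displacement from the measurement origin,
averaged over tracers and then over independent ensembles; no
time-averaging over sliding origins is used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .engine import Trajectory

__all__ = [
    "MSDProfile",
    "DiffusionCharacterization",
    "ensemble_msd",
    "loglog_profile",
    "fit_alpha",
    "apparent_diffusion",
    "instantaneous_diffusion",
    "effective_diffusion",
    "fit_msd_powerlaw",
    "characterize",
    "UM2_PER_MS_TO_NM2_PER_US",
]

#: 1 um^2/ms = 1000 nm^2/us
UM2_PER_MS_TO_NM2_PER_US: float = 1e3

#: |log-log slope| at or below which diffusion is classified normal
FLATNESS_TOL: float = 0.05
#: tail window (fraction of the log-time span) for strongly anomalous fits
TAIL_FRACTION: float = 0.25
#: tail slope at or below which the profile counts as steeply decaying
STEEP_SLOPE: float = -0.5
#: sliding-window width (fraction of the log-time span) for crossover search
WINDOW_FRACTION: float = 0.2


@dataclass
class MSDProfile:
    """Ensemble-averaged <r^2>(t) on a strictly increasing time grid."""

    times_ms: np.ndarray
    msd_um2: np.ndarray
    n_tracers: int
    n_ensembles: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        m = np.asarray(self.msd_um2, dtype=float)
        if t.shape != m.shape:
            raise ValueError("times and msd must have the same shape")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] <= 0):
            raise ValueError("times must be positive and strictly increasing")
        if np.any(m < 0):
            raise ValueError("msd must be non-negative")
        self.times_ms = t
        self.msd_um2 = m


@dataclass
class DiffusionCharacterization:
    """Anomalous exponent, fit constant and effective diffusivity."""

    alpha: float
    d_fit_um2_per_ms: float
    d_eff_um2_per_ms: float
    regime: str  # "normal" | "transition" | "anomalous"
    crossover_time_ms: float | None = None
    crossover_length_um2: float | None = None
    t_obs_ms: float = 2000.0

    @property
    def d_eff_nm2_per_us(self) -> float:
        return self.d_eff_um2_per_ms * UM2_PER_MS_TO_NM2_PER_US


def ensemble_msd(trajectories: Iterable[Trajectory] | Trajectory) -> MSDProfile:
    """Average tracer-mean MSDs over ensembles (unweighted over runs)."""
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("no trajectories given")
    t0 = trajs[0].times_ms
    for tr in trajs[1:]:
        if tr.times_ms.shape != t0.shape or not np.allclose(tr.times_ms, t0):
            raise ValueError("trajectory time grids are not aligned")
    msd = np.mean([tr.msd for tr in trajs], axis=0)
    return MSDProfile(
        times_ms=t0.copy(),
        msd_um2=msd,
        n_tracers=trajs[0].n_tracers,
        n_ensembles=len(trajs),
    )


def loglog_profile(profile: MSDProfile) -> pd.DataFrame:
    """Table of (log t, log(<r^2>/t)); zero-MSD entries are dropped."""
    t = profile.times_ms
    m = profile.msd_um2
    keep = m > 0
    if not np.all(keep):
        import warnings

        warnings.warn(f"dropping {int(np.sum(~keep))} zero-MSD points from log-log profile")
    t, m = t[keep], m[keep]
    return pd.DataFrame({"log_t": np.log(t), "log_msd_over_t": np.log(m / t)})


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def fit_alpha(
    loglog: pd.DataFrame,
    flatness_tol: float = FLATNESS_TOL,
    *,
    tail_fraction: float = TAIL_FRACTION,
    steep_slope: float = STEEP_SLOPE,
    window_fraction: float = WINDOW_FRACTION,
    t_obs_ms: float = 2000.0,
) -> DiffusionCharacterization:
    """Classify a log-log MSD profile and estimate (alpha, D, D_eff).

    Three branches:

    (a) *normal* — global least-squares slope magnitude <= flatness_tol:
        alpha = 1, D from the mean level of log(<r^2>/t).
    (b) *anomalous* — the late-time window (last ``tail_fraction`` of the
        log-time span) has slope <= ``steep_slope``: a long-range power
        law; alpha = 1 + tail slope, D from the tail intercept.
    (c) *transition* — otherwise: an initial anomalous segment crossing
        over to normal diffusion.  Local slopes over sliding windows of
        ``window_fraction`` of the span locate the first time after which
        the profile stays flat; alpha is fitted on the segment before it.
    """
    x = np.asarray(loglog["log_t"], dtype=float)
    y = np.asarray(loglog["log_msd_over_t"], dtype=float)
    if x.size < 10 or (x.size and x[-1] - x[0] < np.log(10.0)):
        raise ValueError("need >= 10 points spanning at least one decade of time")
    span = x[-1] - x[0]

    def _finish(alpha, d, regime, ct=None, cl=None):
        alpha = float(np.clip(alpha, 0.0, 1.05))
        if alpha > 1.0:  # noise slightly above 1 reads as normal diffusion
            alpha, regime = 1.0, "normal"
        if regime == "normal":
            d_eff = d
        else:
            d_eff = apparent_diffusion(d, alpha, t_obs_ms)
        return DiffusionCharacterization(alpha, d, d_eff, regime, ct, cl, t_obs_ms)

    g_slope, _ = _linfit(x, y)
    if abs(g_slope) <= flatness_tol:
        return _finish(1.0, float(np.exp(np.mean(y)) / 4.0), "normal")

    tail = x >= x[-1] - tail_fraction * span
    if np.sum(tail) >= 3:
        t_slope, t_int = _linfit(x[tail], y[tail])
        if t_slope <= steep_slope:
            return _finish(1.0 + t_slope, float(np.exp(t_int) / 4.0), "anomalous")

    # transition: sliding local slopes to find the crossover to flatness
    w = window_fraction * span
    local = np.full(x.size, np.nan)
    for j in range(x.size):
        sel = (x >= x[j]) & (x <= x[j] + w)
        if np.sum(sel) >= 3:
            local[j], _ = _linfit(x[sel], y[sel])
    flat = np.abs(local) <= flatness_tol
    cross_idx = None
    for j in range(x.size):
        if np.isnan(local[j]):
            break
        if np.all(flat[j:][~np.isnan(local[j:])]):
            cross_idx = j
            break
    if cross_idx is None or cross_idx < 3:
        # no sustained flat tail found: fit the first half as the anomalous
        # segment and leave the crossover undetermined
        half = x <= x[0] + 0.5 * span
        s, b = _linfit(x[half], y[half])
        return _finish(1.0 + s, float(np.exp(b) / 4.0), "transition")
    s, b = _linfit(x[:cross_idx], y[:cross_idx])
    ct = float(np.exp(x[cross_idx]))
    cl = float(np.exp(y[cross_idx] + x[cross_idx]))  # MSD value at crossover
    return _finish(1.0 + s, float(np.exp(b) / 4.0), "transition", ct, cl)


def apparent_diffusion(d_fit: float, alpha: float, t_ms: float) -> float:
    """Apparent diffusivity D t^(1-alpha); decreases with t for alpha < 1."""
    if t_ms <= 0:
        raise ValueError("time must be positive")
    return d_fit * t_ms ** (alpha - 1.0)


def instantaneous_diffusion(d_fit: float, alpha: float, t_ms: float) -> float:
    """Instantaneous diffusivity alpha D t^(1-alpha) (= alpha * D_app)."""
    return alpha * apparent_diffusion(d_fit, alpha, t_ms)


def effective_diffusion(char: DiffusionCharacterization, t_obs_ms: float = 2000.0) -> float:
    """D_eff: the fit constant for normal diffusion, D_app(t_obs) otherwise."""
    if t_obs_ms <= 0:
        raise ValueError("observation horizon must be positive")
    if char.regime == "normal":
        return char.d_fit_um2_per_ms
    return apparent_diffusion(char.d_fit_um2_per_ms, char.alpha, t_obs_ms)


def fit_msd_powerlaw(
    times_ms: Sequence[float] | np.ndarray,
    msd_um2: Sequence[float] | np.ndarray,
    method: str = "loglog",
) -> tuple[float, float, float, float]:
    """Fit <r^2> = 4 D t^alpha to a generic MSD table.

    ``method="loglog"`` (default) fits a line in log-log space;
    ``method="nls"`` runs nonlinear least squares on the original scale.
    Returns (alpha, D, se_alpha, se_D).
    """
    t = np.asarray(times_ms, dtype=float)
    m = np.asarray(msd_um2, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points to fit the power law")
    if np.any(t <= 0) or np.any(m <= 0):
        raise ValueError("times and MSD values must be positive")
    if method == "loglog":
        X = np.log(t)
        Y = np.log(m)
        (slope, intercept), cov = np.polyfit(X, Y, 1, cov=True)
        alpha = float(slope)
        d = float(np.exp(intercept) / 4.0)
        se_alpha = float(np.sqrt(cov[0, 0]))
        se_d = d * float(np.sqrt(cov[1, 1]))
        return alpha, d, se_alpha, se_d
    if method == "nls":
        def model(t, alpha, d):
            return 4.0 * d * t**alpha

        p0 = fit_msd_powerlaw(t, m, method="loglog")[:2]
        popt, pcov = curve_fit(model, t, m, p0=p0, maxfev=10000)
        alpha, d = float(popt[0]), float(popt[1])
        se = np.sqrt(np.diag(pcov))
        return alpha, d, float(se[0]), float(se[1])
    raise ValueError(f"unknown fitting method {method!r}")


def characterize(
    profile: MSDProfile,
    flatness_tol: float = FLATNESS_TOL,
    t_obs_ms: float = 2000.0,
    **fit_kwargs,
) -> DiffusionCharacterization:
    """Convenience: log-log transform then three-branch classification."""
    return fit_alpha(loglog_profile(profile), flatness_tol,
                     t_obs_ms=t_obs_ms, **fit_kwargs)


def read_msd_table(path) -> MSDProfile:
    """Read a two-column delimited (t_ms, msd_um2) text table ('#' comments)."""
    df = pd.read_csv(path, comment="#", sep=None, engine="python",
                     header=None, names=["t_ms", "msd_um2"])
    return MSDProfile(df["t_ms"].to_numpy(float), df["msd_um2"].to_numpy(float),
                      n_tracers=0, n_ensembles=0)


def write_msd_table(profile: MSDProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("# ensemble-averaged MSD\n# columns: time [ms], msd [um^2]\n")
        fh.write(f"# n_tracers={profile.n_tracers} n_ensembles={profile.n_ensembles}\n")
        for t, m in zip(profile.times_ms, profile.msd_um2):
            fh.write(f"{t:.9g},{m:.9g}\n")
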