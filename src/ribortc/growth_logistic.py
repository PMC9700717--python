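"""Logistic confluence growth fitting and growth rate at the control cp.

Live-cell imagers report percent confluency over time.  Each replicate
series is fitted with a 4-parameter logistic

    C(t) = A + (K - A) / (1 + exp(-r (t - t0)))

where A is the baseline confluency (%), K the plateau (%), r the intrinsic
rate (per h) and t0 the inflection time (h).  The growth rate dC/dt of a
logistic is maximal at t0; the untreated control's inflection time is the
*critical point* (cp), and every condition's growth rate is evaluated at
the control cp and expressed in %confluency/h:

    dC/dt(t) = r (K - A) exp(-r (t - t0)) / (1 + exp(-r (t - t0)))^2

so the control evaluated at its own cp grows at r (K - A) / 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ConfluenceSeries",
    "GrowthFit",
    "fit_logistic",
    "logistic_rate",
    "rate_at_control_cp",
    "read_confluence_tsv",
    "write_confluence_tsv",
]

MIN_POINTS = 6
K_UPPER = 100.0 * 1.05  # small headroom above 100% for noisy plateaus


@dataclass
class ConfluenceSeries:
    """One replicate's confluence time course (% in [0,100])."""

    condition: str
    replicate: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class GrowthFit:
    """Fitted logistic parameters for one replicate."""

    condition: str
    replicate: str
    A: float
    K: float
    r: float
    t0: float
    converged: bool
    residual_sd: float
    message: str = ""

    @property
    def cp(self) -> float:
        """Inflection time: where this curve's own growth rate is maximal."""
        return self.t0

    @property
    def rate_at_own_cp(self) -> float:
        return self.r * (self.K - self.A) / 4.0


def _logistic(t, A, K, r, t0):
    return A + (K - A) / (1.0 + np.exp(-r * (t - t0)))


def logistic_rate(fit: GrowthFit, t: float) -> float:
    """dC/dt of the fitted logistic at time ``t`` (%confluency/h)."""
    z = np.exp(-fit.r * (t - fit.t0))
    return float(fit.r * (fit.K - fit.A) * z / (1.0 + z) ** 2)


def fit_logistic(series: ConfluenceSeries) -> GrowthFit:
    """Least-squares 4-parameter logistic fit of one replicate series.

    Initialization: A = min(C), K = max(C), t0 at the half-range crossing,
    r from the central finite-difference slope at t0.  Bounds keep A >= 0,
    K <= 105 and r > 0.  Non-convergence (or a degenerate K <= A solution)
    returns ``converged=False`` with a message rather than silent output.
    """
    t, c = series.times, series.values
    if len(t) < MIN_POINTS:
        raise ValueError(
            f"{series.condition}/{series.replicate}: need >= {MIN_POINTS} time points"
        )
    rng_c = float(np.ptp(c))
    if rng_c < 1e-8:
        return GrowthFit(series.condition, series.replicate,
                         A=float(c[0]), K=float(c[0]), r=0.0, t0=float(t[0]),
                         converged=False, residual_sd=0.0, message="no growth")
    a0, k0 = float(c.min()), float(c.max())
    half = a0 + rng_c / 2.0
    i_half = int(np.argmin(np.abs(c - half)))
    t0_0 = float(t[i_half])
    i_lo, i_hi = max(i_half - 1, 0), min(i_half + 1, len(t) - 1)
    slope = (c[i_hi] - c[i_lo]) / (t[i_hi] - t[i_lo])
    # dC/dt at t0 equals r (K - A) / 4
    r0 = float(np.clip(4.0 * abs(slope) / max(rng_c, 1e-9), 1e-4, 5.0))
    try:
        popt, _ = curve_fit(
            _logistic, t, c,
            p0=[a0, k0, r0, t0_0],
            bounds=([0.0, 0.0, 1e-9, t[0] - 2 * (t[-1] - t[0])],
                    [K_UPPER, K_UPPER, 50.0, t[-1] + 2 * (t[-1] - t[0])]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return GrowthFit(series.condition, series.replicate,
                         A=np.nan, K=np.nan, r=np.nan, t0=np.nan,
                         converged=False, residual_sd=np.nan, message=str(exc))
    A, K, r, t0 = (float(v) for v in popt)
    resid_sd = float(np.std(c - _logistic(t, A, K, r, t0), ddof=min(4, len(t) - 1)))
    if K <= A or r <= 0:
        return GrowthFit(series.condition, series.replicate, A, K, r, t0,
                         converged=False, residual_sd=resid_sd,
                         message="degenerate fit (K <= A or r <= 0)")
    return GrowthFit(series.condition, series.replicate, A, K, r, t0,
                     converged=True, residual_sd=resid_sd)


def rate_at_control_cp(fits: list[GrowthFit], control_id: str) -> pd.DataFrame:
    """Growth rate of every replicate at the control's critical point.

    cp is the mean inflection time t0 over converged control replicates
    (replicates are fitted independently).  Returns one row per replicate
    with its rate at cp (%confluency/h; NaN for unconverged fits) plus a
    ``cp_h`` column.  An unconverged control is fatal.
    """
    control = [f for f in fits if f.condition == control_id]
    if not control:
        raise ValueError(f"no fits for control condition {control_id!r}")
    conv = [f for f in control if f.converged]
    if not conv:
        raise ValueError(f"control condition {control_id!r} has no converged fit")
    cp = float(np.mean([f.t0 for f in conv]))
    rows = []
    for f in fits:
        rows.append(
            {
                "condition": f.condition,
                "replicate": f.replicate,
                "cp_h": cp,
                "rate_at_cp": logistic_rate(f, cp) if f.converged else np.nan,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)


def summarize_rates(rates: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean +- SEM of the rate at cp over replicates."""
    g = rates.groupby("condition")["rate_at_cp"]
    out = g.agg(n="count", mean_rate="mean", sd="std").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"].clip(lower=1))
    return out.drop(columns="sd")


def read_confluence_tsv(path: str | Path) -> list[ConfluenceSeries]:
    """Read a TSV with columns time_h, condition, replicate, confluence_pct."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            ConfluenceSeries(condition=str(cond), replicate=str(rep),
                             times=grp["time_h"].to_numpy(),
                             values=grp["confluence_pct"].to_numpy())
        )
    return out


def write_confluence_tsv(series: list[ConfluenceSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for t, c in zip(s.times, s.values):
            rows.append({"time_h": t, "condition": s.condition,
                         "replicate": s.replicate, "confluence_pct": c})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
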