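"""Smoothing and Extraction of Traits (SET) for projected shoot area series.

Projected shoot area (PSA, kpixels) is the sum of plant pixels over the three
used camera views of a half-pot.  Raw daily PSA is noisy, so each half-pot
series is smoothed with a natural cubic smoothing spline whose equivalent
degrees of freedom (the trace of the smoother matrix) are fixed, df = 5 by
default ("moderate smoothing").  Traits are then read off the smoothed curve
(sPSA): absolute growth AG = sPSA at the final day, and interval relative
growth rates

    RGR(t1, t2) = ln[sPSA(t2) / sPSA(t1)] / (t2 - t1)   (per day)

for successive pairs of extraction days.  A bare log-ratio convention (no
division by interval length) is available by flag.

The smoother follows the Reinsch/Green-Silverman formulation: with strictly
increasing days x_1 < ... < x_n the fitted values are

    f_hat = (I + lam * K)^{-1} y,      K = D' W^{-1} D,

where D is the (n-2) x n second-difference operator scaled by the knot
spacings and W the tridiagonal Gram matrix of the natural-spline second
derivatives.  trace S(lam) decreases continuously from n (lam -> 0,
interpolation) to 2 (lam -> inf, the least-squares straight line); lam is
solved from trace S(lam) = df by bracketed root finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import CubicSpline

__all__ = [
    "PsaSeries",
    "GrowthTraits",
    "ProxyFit",
    "DEFAULT_DF",
    "DEFAULT_EXTRACTION_DAYS",
    "USED_VIEWS",
    "natural_spline_penalty",
    "smoother_matrix",
    "solve_lambda_for_df",
    "aggregate_psa",
    "aggregate_psa_table",
    "smooth_psa",
    "smooth_table",
    "extract_traits",
    "traits_table",
    "validate_proxy",
]

DEFAULT_DF = 5.0
DEFAULT_EXTRACTION_DAYS = (35, 40, 50, 60, 70)
#: the three camera views whose half-images are summed into half-pot PSA
USED_VIEWS = ("top", "side1", "side2")

TRACE_TOL = 1e-6


@dataclass
class PsaSeries:
    """One half-pot's PSA time series on its observed day grid."""

    half_pot_id: str
    days: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray | None = None
    df_used: float | None = None
    lam: float | None = None
    missing_days: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.days.ndim != 1 or self.days.shape != self.raw.shape:
            raise ValueError("days and raw must be 1-D arrays of equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if not np.all(np.isfinite(self.raw)):
            raise ValueError("raw PSA contains non-finite values")
        if np.any(self.raw < 0):
            raise ValueError("raw PSA must be non-negative")

    def smoothed_at(self, day: float | np.ndarray) -> np.ndarray:
        """Interpolate the fitted spline at arbitrary days inside the range.

        The smoothing spline is itself a natural cubic spline, so the natural
        cubic interpolant through the fitted values reproduces it exactly.
        """
        if self.smoothed is None:
            raise ValueError("series has not been smoothed")
        day = np.asarray(day, dtype=float)
        if np.any(day < self.days[0]) or np.any(day > self.days[-1]):
            raise ValueError("extraction day outside the smoothed range")
        cs = CubicSpline(self.days, self.smoothed, bc_type="natural")
        return cs(day)


@dataclass
class GrowthTraits:
    """Extracted traits for one half-pot: sPSA at the chosen days, AG, RGRs."""

    half_pot_id: str
    days: tuple[int, ...]
    spsa: dict[int, float]
    ag: float
    rgr: dict[tuple[int, int], float]
    per_day: bool
    undefined_intervals: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class ProxyFit:
    """OLS validation of image-derived AG against harvested biomass."""

    grouping: str
    r2: float
    slope: float
    intercept: float
    n: int


def natural_spline_penalty(x: np.ndarray) -> np.ndarray:
    """Penalty matrix K with f' K f = integral of f''(t)^2 dt.

    K = D' W^{-1} D in the Green-Silverman band form, built from the knot
    spacings h_i = x_{i+1} - x_i.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        return np.zeros((n, n))
    h = np.diff(x)
    # D: (n-2) x n second-difference operator
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    # W: (n-2) x (n-2) tridiagonal Gram matrix
    W = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        W[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < n - 2:
            W[i, i + 1] = W[i + 1, i] = h[i + 1] / 6.0
    return D.T @ np.linalg.solve(W, D)


def smoother_matrix(x: np.ndarray, lam: float) -> np.ndarray:
    """S(lam) = (I + lam K)^{-1}; fitted values are S y."""
    K = natural_spline_penalty(x)
    n = K.shape[0]
    return np.linalg.inv(np.eye(n) + lam * K)


def _trace_smoother(x: np.ndarray, lam: float) -> float:
    return float(np.trace(smoother_matrix(x, lam)))


def solve_lambda_for_df(x: np.ndarray, df: float, tol: float = TRACE_TOL) -> float:
    """Solve trace S(lam) = df for lam by bracketed root finding.

    trace S is continuous and strictly decreasing in lam, from n at lam = 0
    to 2 as lam -> inf, so a root exists for any df in (2, n).  Brent's
    method on log10(lam) with an expanding bracket; bisection is the
    fallback inside scipy's brentq.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if not (2.0 < df <= n):
        raise ValueError(f"df must lie in (2, {n}], got {df}")
    if df == n:
        return 0.0

    def g(log_lam: float) -> float:
        return _trace_smoother(x, 10.0**log_lam) - df

    lo, hi = -12.0, 12.0
    while g(lo) < 0 and lo > -300:
        lo -= 12.0
    while g(hi) > 0 and hi < 300:
        hi += 12.0
    log_lam = optimize.brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16)
    lam = 10.0**log_lam
    # polish until the trace equation holds to tol
    if abs(_trace_smoother(x, lam) - df) > tol:
        lam = 10.0 ** optimize.brentq(g, log_lam - 1.0, log_lam + 1.0, xtol=1e-15, rtol=8.9e-16)
    return lam


def _line_smoother(x: np.ndarray) -> np.ndarray:
    """Hat matrix of the least-squares straight line: the lam -> inf limit."""
    B = np.column_stack([np.ones_like(x), x])
    return B @ np.linalg.solve(B.T @ B, B.T)


def _smoother_for(x: np.ndarray, df: float) -> tuple[float, np.ndarray]:
    """(lam, S) for a day grid; df = 2 is the straight-line limit."""
    if df == 2.0:
        return np.inf, _line_smoother(np.asarray(x, dtype=float))
    lam = solve_lambda_for_df(x, df)
    return lam, smoother_matrix(x, lam)


def aggregate_psa(view_pixels: dict[str, float]) -> float:
    """Half-pot PSA for one day: the sum over the three used views.

    Raises if any of the used views is absent; callers flag such days as
    missing and exclude them from the smoothing input.
    """
    missing = [v for v in USED_VIEWS if v not in view_pixels]
    if missing:
        raise ValueError(f"missing view(s) {missing}; day must be flagged absent")
    return float(sum(view_pixels[v] for v in USED_VIEWS))


def aggregate_psa_table(psa: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate a long view-level table to half-pot daily PSA.

    Input columns: half_pot_id, DAP, view, kpixels.  Days with fewer than the
    three used views are flagged and excluded.  Duplicate (half_pot, day,
    view) rows are averaged before summation.  Returns (aggregated, flagged)
    with aggregated columns half_pot_id, DAP, psa.
    """
    dedup = (
        psa.groupby(["half_pot_id", "DAP", "view"], as_index=False)["kpixels"].mean()
    )
    counts = dedup.groupby(["half_pot_id", "DAP"])["view"].nunique()
    agg = dedup.groupby(["half_pot_id", "DAP"], as_index=False)["kpixels"].sum()
    agg = agg.rename(columns={"kpixels": "psa"})
    ok = counts[counts == len(USED_VIEWS)].reset_index()[["half_pot_id", "DAP"]]
    flagged = counts[counts != len(USED_VIEWS)].reset_index()[["half_pot_id", "DAP"]]
    agg = agg.merge(ok, on=["half_pot_id", "DAP"])
    return agg.sort_values(["half_pot_id", "DAP"]).reset_index(drop=True), flagged


def smooth_psa(series: PsaSeries, df: float = DEFAULT_DF, scale: str = "raw") -> PsaSeries:
    """Smooth one series with a natural cubic smoothing spline at fixed df.

    scale="raw" smooths the PSA values directly; scale="log" smooths
    ln(PSA + 1) and exponentiates back (for positivity-preserving smoothing
    of strongly multiplicative noise).  df = 2 is accepted as the
    infinite-penalty limit and returns the least-squares straight line.
    """
    x, y = series.days, series.raw
    if x.size < 4:
        raise ValueError(f"need >= 4 distinct days to smooth, got {x.size}")
    if scale not in ("raw", "log"):
        raise ValueError(f"scale must be 'raw' or 'log', got {scale!r}")
    lam, S = _smoother_for(x, df)
    if scale == "log":
        fitted = np.expm1(S @ np.log1p(y))
    else:
        fitted = S @ y
    return PsaSeries(
        half_pot_id=series.half_pot_id,
        days=x,
        raw=y,
        smoothed=fitted,
        df_used=df,
        lam=lam,
        missing_days=list(series.missing_days),
    )


def smooth_table(
    agg: pd.DataFrame, df: float = DEFAULT_DF, scale: str = "raw"
) -> dict[str, PsaSeries]:
    """Smooth every half-pot of an aggregated PSA table independently.

    lam depends only on the day grid, so it is solved once per distinct grid
    and the smoother matrix reused across half-pots sharing it.
    """
    out: dict[str, PsaSeries] = {}
    smoother_cache: dict[tuple, tuple[float, np.ndarray]] = {}
    for hp, grp in agg.groupby("half_pot_id", sort=True):
        grp = grp.sort_values("DAP")
        x = grp["DAP"].to_numpy(dtype=float)
        y = grp["psa"].to_numpy(dtype=float)
        key = tuple(x)
        if key not in smoother_cache:
            smoother_cache[key] = _smoother_for(x, df)
        lam, S = smoother_cache[key]
        fitted = np.expm1(S @ np.log1p(y)) if scale == "log" else S @ y
        out[str(hp)] = PsaSeries(
            half_pot_id=str(hp), days=x, raw=y, smoothed=fitted, df_used=df, lam=lam
        )
    return out


def extract_traits(
    series: PsaSeries,
    days: tuple[int, ...] = DEFAULT_EXTRACTION_DAYS,
    per_day: bool = True,
) -> GrowthTraits:
    """Read sPSA, AG and interval RGRs off a smoothed series.

    RGR for an interval is defined only where both endpoint sPSA values are
    positive; other intervals are flagged undefined (NaN).
    """
    days = tuple(int(d) for d in days)
    values = series.smoothed_at(np.asarray(days, dtype=float))
    spsa = {d: float(v) for d, v in zip(days, values)}
    ag = spsa[days[-1]]
    rgr: dict[tuple[int, int], float] = {}
    undefined: list[tuple[int, int]] = []
    for t1, t2 in zip(days[:-1], days[1:]):
        if spsa[t1] > 0 and spsa[t2] > 0:
            lr = float(np.log(spsa[t2] / spsa[t1]))
            rgr[(t1, t2)] = lr / (t2 - t1) if per_day else lr
        else:
            rgr[(t1, t2)] = float("nan")
            undefined.append((t1, t2))
    return GrowthTraits(
        half_pot_id=series.half_pot_id,
        days=days,
        spsa=spsa,
        ag=ag,
        rgr=rgr,
        per_day=per_day,
        undefined_intervals=undefined,
    )


def traits_table(
    smoothed: dict[str, PsaSeries],
    days: tuple[int, ...] = DEFAULT_EXTRACTION_DAYS,
    per_day: bool = True,
) -> pd.DataFrame:
    """Trait table, one row per half-pot: sPSA_d columns, AG, RGR_t1_t2."""
    rows = []
    for hp in sorted(smoothed):
        tr = extract_traits(smoothed[hp], days=days, per_day=per_day)
        row: dict[str, object] = {"half_pot_id": hp}
        for d in tr.days:
            row[f"sPSA_{d}"] = tr.spsa[d]
        row["AG"] = tr.ag
        for (t1, t2), v in tr.rgr.items():
            row[f"RGR_{t1}_{t2}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def validate_proxy(
    traits: pd.DataFrame,
    harvest: pd.DataFrame,
    design: pd.DataFrame,
    grouping: str = "whole-pot",
) -> ProxyFit:
    """OLS of harvested dry biomass (AGB, g) on image-derived AG (kpixels).

    grouping selects the validation subset: "grass" / "legume" use matched
    half-pots of that species; "whole-pot" sums the two halves of each pot
    (both AG and AGB) before fitting.
    """
    merged = traits[["half_pot_id", "AG"]].merge(
        harvest[["half_pot_id", "AGB"]], on="half_pot_id"
    )
    merged = merged.merge(
        design[["half_pot_id", "pot_id", "species"]], on="half_pot_id"
    )
    if grouping == "whole-pot":
        pots = merged.groupby("pot_id", as_index=False)[["AG", "AGB"]].sum()
        # only pots with both halves harvested contribute a complete sum
        n_halves = merged.groupby("pot_id")["half_pot_id"].count()
        pots = pots[pots["pot_id"].isin(n_halves[n_halves == 2].index)]
        x, y = pots["AG"].to_numpy(), pots["AGB"].to_numpy()
    elif grouping in ("grass", "legume"):
        sub = merged[merged["species"] == grouping]
        x, y = sub["AG"].to_numpy(), sub["AGB"].to_numpy()
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if x.size < 3:
        raise ValueError(f"need >= 3 matched pairs, got {x.size}")
    res = stats.linregress(x, y)
    return ProxyFit(
        grouping=grouping,
        r2=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=int(x.size),
    )
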