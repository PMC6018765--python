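"""HNF growth-kinetics estimation from abundance/biovolume time series.

Maximum growth rate mu_max is the steepest least-squares slope of ln(HNF)
vs time over a contiguous sampling window ending no later than the observed
HNF maximum; doubling time DT = ln2/mu; the lag phase is where the fitted
log-linear line crosses the zero-time abundance level; volumetric gross
growth efficiency (GGE) compares HNF biovolume gained with bacterial
biovolume lost between t0 and the HNF biovolume peak; relative growth rates
express each treatment's net HNF increase against the fastest treatment,
evaluated at that reference's peak time and set to 100 % for the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AbundanceSeries",
    "ExponentialFit",
    "SegmentedFit",
    "GrowthParams",
    "fit_exponential_window",
    "fit_lagged_exponential",
    "doubling_time",
    "lag_phase",
    "relative_growth_rate",
    "gross_growth_efficiency",
    "summarize_growth",
]


@dataclass
class AbundanceSeries:
    """One replicate's bacteria/HNF abundance time course.

    times in h (strictly increasing from 0); abundances in cells ml^-1
    (all positive); optional mean cell volumes (um^3) enable biovolume work.
    """

    treatment: str
    replicate: int
    times: np.ndarray
    bacteria: np.ndarray
    hnf: np.ndarray
    bact_mcv: np.ndarray | None = None
    hnf_mcv: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bacteria = np.asarray(self.bacteria, dtype=float)
        self.hnf = np.asarray(self.hnf, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least two sampling times")
        if self.times[0] != 0:
            raise ValueError("time series must start at t0 = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        for name in ("bacteria", "hnf"):
            v = getattr(self, name)
            if v.shape != self.times.shape:
                raise ValueError(f"{name} must match times in length")
            if np.any(v <= 0):
                raise ValueError(f"{name} abundances must be positive")
        for name in ("bact_mcv", "hnf_mcv"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.times.shape or np.any(v <= 0):
                    raise ValueError(f"{name} must be positive and match times")
                setattr(self, name, v)

    @property
    def hnf_biovolume(self) -> np.ndarray:
        if self.hnf_mcv is None:
            raise ValueError("hnf_mcv required for biovolume")
        return self.hnf * self.hnf_mcv

    @property
    def bact_biovolume(self) -> np.ndarray:
        if self.bact_mcv is None:
            raise ValueError("bact_mcv required for biovolume")
        return self.bacteria * self.bact_mcv


@dataclass(frozen=True)
class ExponentialFit:
    window: tuple[int, int]  # inclusive index pair into the series
    slope: float  # h^-1
    intercept: float  # ln(cells ml^-1) at t = 0
    r2: float
    degraded: bool = False  # no window met the r2 gate


@dataclass
class GrowthParams:
    """Estimated growth parameters for one replicate."""

    treatment: str
    replicate: int
    mu_max: float  # h^-1
    doubling_time: float  # h
    lag: float  # h
    gge: float  # fraction; nan if not estimable
    relative_growth: float = math.nan  # %, filled at treatment level
    window: tuple[int, int] = (0, 0)
    r2: float = math.nan
    degraded: bool = False


def _loglinear(t: np.ndarray, ln_n: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line through (t, ln N); r2 = 1 for a perfect fit
    (including the flat case where total variance vanishes)."""
    res = stats.linregress(t, ln_n)
    pred = res.intercept + res.slope * t
    ss_res = float(np.sum((ln_n - pred) ** 2))
    ss_tot = float(np.sum((ln_n - ln_n.mean()) ** 2))
    r2 = 1.0 if ss_tot < 1e-30 else 1.0 - ss_res / ss_tot
    return float(res.slope), float(res.intercept), r2


def fit_exponential_window(
    series: AbundanceSeries,
    min_points: int = 3,
    r2_min: float = 0.95,
) -> ExponentialFit:
    """Steepest log-linear window of the HNF time course.

    Candidate windows are contiguous runs of >= min_points samples ending at
    or before the observed HNF maximum.  Among windows whose ln-linear fit
    reaches r2 >= r2_min the one with the largest slope wins (longest window
    on ties); if none passes the gate the max-slope window is returned with
    ``degraded=True``.
    """
    n = len(series.times)
    if n < min_points:
        raise ValueError(f"need at least {min_points} samples")
    ln_n = np.log(series.hnf)
    i_max = int(np.max(np.flatnonzero(series.hnf == series.hnf.max())))
    end_cap = max(i_max, min_points - 1)  # always allow at least one window

    candidates = []
    for j in range(min_points - 1, end_cap + 1):
        for i in range(0, j - min_points + 2):
            slope, intercept, r2 = _loglinear(series.times[i : j + 1], ln_n[i : j + 1])
            candidates.append(((i, j), slope, intercept, r2))

    gated = [c for c in candidates if c[3] >= r2_min]
    pool, degraded = (gated, False) if gated else (candidates, True)
    # max slope; ties broken by window length (longer first)
    best = max(pool, key=lambda c: (c[1], c[0][1] - c[0][0]))
    return ExponentialFit(window=best[0], slope=best[1], intercept=best[2],
                          r2=best[3], degraded=degraded)


@dataclass(frozen=True)
class SegmentedFit:
    """Pooled flat-exponential-plateau fit over the replicates of a treatment.

    The model for each replicate r is
    ln N_r(t) = a_r + mu * clip(min(t, tau) - lag, 0, inf):
    constant during the lag, log-linear growth at a common rate mu, and a
    plateau after the saturation time tau once prey is exhausted.  lag and
    tau are shared across replicates (they are properties of the treatment);
    intercepts are per replicate.
    """

    mu: float  # pooled growth rate, h^-1
    lag: float  # h
    saturation_time: float  # h
    mu_per_replicate: tuple[float, ...]
    intercepts: tuple[float, ...]
    sse: float


def _segmented_sse(
    knots: tuple[float, float],
    t: np.ndarray,
    ln_courses: list[np.ndarray],
    lag_max: float,
) -> tuple[float, float, list[float], list[float]]:
    lag, tau = knots
    if not (0.0 <= lag <= lag_max and lag + 1.0 < tau <= t[-1]):
        return np.inf, 0.0, [], []
    x = np.clip(np.minimum(t, tau) - lag, 0.0, None)
    xc = x - x.mean()
    varx = float((xc**2).sum())
    if varx <= 0:
        return np.inf, 0.0, [], []
    slopes, intercepts, sse = [], [], 0.0
    cov_total = 0.0
    for ln in ln_courses:
        yc = ln - ln.mean()
        cov = float(xc @ yc)
        cov_total += cov
        slopes.append(cov / varx)
    mu = cov_total / (varx * len(ln_courses))
    for ln, s in zip(ln_courses, slopes):
        yc = ln - ln.mean()
        sse += float(((yc - s * xc) ** 2).sum())
        intercepts.append(float(ln.mean() - s * x.mean()))
    return sse, mu, slopes, intercepts


def fit_lagged_exponential(replicates: list[AbundanceSeries]) -> SegmentedFit:
    """Fit the shared lag/growth/plateau model to a treatment's replicates.

    The lag and saturation knots are profiled on a coarse grid and refined by
    Nelder-Mead; slopes and intercepts are closed-form least squares at each
    knot pair.  Noise-free exponential data are recovered exactly.  Needs at
    least four sampling times.
    """
    if not replicates:
        raise ValueError("at least one replicate required")
    t = replicates[0].times
    for s in replicates[1:]:
        if not np.array_equal(s.times, t):
            raise ValueError("replicates must share a sampling grid")
    if len(t) < 4:
        raise ValueError("segmented fit needs at least four sampling times")
    lns = [np.log(s.hnf) for s in replicates]
    lag_max = float(t[2])  # lag cannot plausibly exceed the third sample

    best = (np.inf, (0.0, t[-1]))
    for lag in np.arange(0.0, lag_max + 1e-9, 0.25):
        for tau in np.arange(lag + 2.0, t[-1] + 1e-9, 1.0):
            sse = _segmented_sse((lag, tau), t, lns, lag_max)[0]
            if sse < best[0]:
                best = (sse, (lag, tau))
    res = optimize.minimize(
        lambda k: _segmented_sse((k[0], k[1]), t, lns, lag_max)[0],
        best[1], method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-12},
    )
    knots = tuple(res.x) if res.fun < best[0] else best[1]
    sse, mu, slopes, intercepts = _segmented_sse(knots, t, lns, lag_max)
    return SegmentedFit(
        mu=mu, lag=float(knots[0]), saturation_time=float(knots[1]),
        mu_per_replicate=tuple(slopes), intercepts=tuple(intercepts), sse=sse,
    )


def doubling_time(mu: float) -> float:
    """DT = ln 2 / mu (h)."""
    if mu <= 0:
        raise ValueError("growth rate must be positive")
    return math.log(2.0) / mu


def lag_phase(slope: float, intercept: float, n0: float) -> float:
    """Lag (h): where the fitted ln-linear growth line crosses ln(n0).

    Negative algebraic lags (line already above the zero-time level at t=0)
    are clamped to 0.
    """
    if slope <= 0:
        raise ValueError("lag is defined only for positive growth slopes")
    if n0 <= 0:
        raise ValueError("zero-time abundance must be positive")
    return max(0.0, (math.log(n0) - intercept) / slope)


def _mean_hnf_course(replicates: list[AbundanceSeries]) -> tuple[np.ndarray, np.ndarray]:
    times = replicates[0].times
    for s in replicates[1:]:
        if not np.array_equal(s.times, times):
            raise ValueError("replicates must share a sampling grid")
    return times, np.mean([s.hnf for s in replicates], axis=0)


def relative_growth_rate(
    series_by_treatment: dict[str, list[AbundanceSeries]],
) -> dict[str, float]:
    """Net HNF increase of each treatment relative to the fastest one (%).

    The reference treatment is the one with the largest replicate-mean net
    increase (peak minus t0); every treatment is scored as 100 x its net
    increase *evaluated at the reference's peak time* over the reference's
    net increase.  The reference scores exactly 100; negative net changes
    clamp to 0.
    """
    if not series_by_treatment:
        raise ValueError("at least one treatment required")
    courses = {t: _mean_hnf_course(reps) for t, reps in series_by_treatment.items()}
    net = {t: float(h.max() - h[0]) for t, (x, h) in courses.items()}
    ref = max(net, key=net.get)
    if net[ref] <= 0:
        raise ValueError("no treatment shows a positive net HNF increase")
    t_ref, h_ref = courses[ref]
    t_peak = t_ref[int(np.argmax(h_ref))]
    scores = {}
    for t, (x, h) in courses.items():
        at_peak = float(np.interp(t_peak, x, h) - h[0])
        scores[t] = 100.0 if t == ref else max(0.0, 100.0 * at_peak / net[ref])
    return scores


def gross_growth_efficiency(series: AbundanceSeries) -> float:
    """Volumetric GGE over the window t0 -> HNF-biovolume peak.

    GGE = HNF biovolume gained / bacterial biovolume lost.  Returns NaN
    (flagged missing) when the HNF peak is at t0 or the bacterial biovolume
    did not decline over the window — the quotient is then meaningless.
    No correction is made for bacterial production within the window.
    """
    bv_h = series.hnf_biovolume
    bv_b = series.bact_biovolume
    i_peak = int(np.max(np.flatnonzero(bv_h == bv_h.max())))
    if i_peak == 0:
        return math.nan
    gained = bv_h[i_peak] - bv_h[0]
    lost = bv_b[0] - bv_b[i_peak]
    if lost <= 0 or gained <= 0:
        return math.nan
    return float(gained / lost)


def _shared_peak_gge(reps: list[AbundanceSeries]) -> list[float]:
    """Per-replicate GGE with the peak index chosen on the replicate-mean
    HNF-biovolume course (avoids the noise-maximum selection bias a per-
    replicate argmax would incur)."""
    try:
        bvh_mean = np.mean([s.hnf_biovolume for s in reps], axis=0)
    except ValueError:
        return [math.nan] * len(reps)
    i_peak = int(np.argmax(bvh_mean))
    out = []
    for s in reps:
        if i_peak == 0:
            out.append(math.nan)
            continue
        gained = s.hnf_biovolume[i_peak] - s.hnf_biovolume[0]
        lost = s.bact_biovolume[0] - s.bact_biovolume[i_peak]
        out.append(float(gained / lost) if (gained > 0 and lost > 0) else math.nan)
    return out


def summarize_growth(
    series_by_treatment: dict[str, list[AbundanceSeries]],
    min_points: int = 3,
    r2_min: float = 0.95,
    method: str = "segmented",
) -> pd.DataFrame:
    """Per-replicate growth parameters plus per-treatment mean and SD rows.

    method='segmented' (default) fits the pooled lag/growth/plateau model
    (:func:`fit_lagged_exponential`): per-replicate slopes with shared lag
    and saturation knots, and GGE evaluated at the replicate-mean biovolume
    peak.  method='window' fits each replicate independently with the
    classical steepest-log-linear-window rule (``min_points``/``r2_min``)
    and derives the lag from the line-intercept construction.  Replicate
    rows carry statistic='replicate'; treatment rows carry 'mean' and 'sd'.
    Relative growth rates are computed across treatments on replicate-mean
    courses and attached to every row of the treatment.
    """
    if method not in ("segmented", "window"):
        raise ValueError("method must be 'segmented' or 'window'")
    rel = relative_growth_rate(series_by_treatment)
    rows = []
    for treatment, reps in series_by_treatment.items():
        use_segmented = method == "segmented" and len(reps[0].times) >= 4
        if use_segmented:
            seg = fit_lagged_exponential(reps)
        gges = _shared_peak_gge(reps) if use_segmented else [None] * len(reps)
        for s, gge_shared in zip(reps, gges):
            if use_segmented:
                mu, lag = seg.mu_per_replicate[reps.index(s)], seg.lag
                r2, degraded, window = math.nan, False, (0, len(s.times) - 1)
                gge = gge_shared
            else:
                fit = fit_exponential_window(s, min_points=min_points, r2_min=r2_min)
                mu = fit.slope
                lag = (lag_phase(mu, fit.intercept, s.hnf[0]) if mu > 0 else math.nan)
                r2, degraded, window = fit.r2, fit.degraded, fit.window
                try:
                    gge = gross_growth_efficiency(s)
                except ValueError:
                    gge = math.nan
            dt = doubling_time(mu) if mu > 0 else math.nan
            rows.append(
                {
                    "treatment": treatment,
                    "replicate": s.replicate,
                    "statistic": "replicate",
                    "mu_max": mu,
                    "doubling_time": dt,
                    "lag": lag,
                    "gge": gge,
                    "relative_growth": rel[treatment],
                    "window_start": window[0],
                    "window_end": window[1],
                    "r2": r2,
                    "degraded": degraded,
                }
            )
    df = pd.DataFrame(rows)
    params = ["mu_max", "doubling_time", "lag", "gge", "relative_growth"]
    summaries = []
    for treatment, g in df.groupby("treatment", sort=False):
        for stat, fn in (("mean", np.nanmean), ("sd", lambda v: np.nanstd(v, ddof=0))):
            row = {"treatment": treatment, "replicate": -1, "statistic": stat}
            row.update({p: float(fn(g[p].to_numpy(dtype=float))) for p in params})
            summaries.append(row)
    return pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)
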