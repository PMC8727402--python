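"""Grid-search detection of a cold-temperature yield threshold (T_C).

For a candidate threshold ``tc`` the cold-day percentage of season ``t`` is

    P_t(tc) = 100 * #{reproductive-period days with Tmin <= tc} / #days,

and the frost-affected yield is regressed on it by ordinary least squares:

    YF_t = b0 + b1 * P_t(tc) + b2 * R_t + e_t,

with R_t the reproductive-period rainfall.  The threshold is scanned over
0.0-19.0 degC in 0.1 degC steps; the candidate with the smallest two-sided
p-value for b1 is selected (ties resolved to the warmest candidate), and a
detection is declared only if that p-value is below 0.05 and the selected
threshold lies between the first and third quartiles of the pooled
reproductive-period minima.  b1 is the yield change (kg/ha) per one
percentage-point increase in cold days, rainfall held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SeasonRecord",
    "ThresholdScan",
    "ThresholdResult",
    "EffectReport",
    "GeoRegression",
    "percent_cold_days",
    "fit_yield_regression",
    "scan_thresholds",
    "select_threshold",
    "quantify_effect",
    "spatial_threshold_regression",
    "detect_threshold",
]

P_TIE_TOL = 1e-12


@dataclass
class SeasonRecord:
    """One season: frost-affected yield, RP rainfall and RP daily minima."""

    year: int
    yf: float
    r: float
    rp_tmin: np.ndarray

    def __post_init__(self) -> None:
        self.rp_tmin = np.asarray(self.rp_tmin, dtype=float)
        if self.rp_tmin.size == 0:
            raise ValueError(f"season {self.year}: empty reproductive period")
        if self.r < 0:
            raise ValueError(f"season {self.year}: negative rainfall")
        if self.yf < 0:
            raise ValueError(f"season {self.year}: negative yield")

    @property
    def rp_days(self) -> int:
        return int(self.rp_tmin.size)


@dataclass
class ThresholdScan:
    """Per-candidate regression results over the T_C grid."""

    grid: np.ndarray
    beta1: np.ndarray        # NaN where unfittable
    p_value: np.ndarray      # NaN where unfittable
    log_p: np.ndarray        # log p-values (selection uses these; -inf = exact fit)
    fittable: np.ndarray     # boolean

    @property
    def n_fittable(self) -> int:
        return int(self.fittable.sum())


@dataclass
class ThresholdResult:
    detected: bool
    tc: Optional[float] = None
    beta0: Optional[float] = None
    beta1: Optional[float] = None
    beta2: Optional[float] = None
    p_beta1: Optional[float] = None
    q1: Optional[float] = None
    q3: Optional[float] = None


@dataclass
class EffectReport:
    tc: float
    beta0: float
    beta1: float
    beta2: float
    p_beta1: float
    yield_loss_expected: bool


@dataclass
class GeoRegression:
    intercept: float
    lat_coef: float
    lon_coef: float
    p_intercept: float
    p_lat: float
    p_lon: float
    n_sites: int


def percent_cold_days(record: SeasonRecord, tc: float) -> float:
    """Percentage of RP days with Tmin at or below ``tc``."""
    if record.rp_days == 0:
        raise ValueError("empty reproductive period")
    return 100.0 * float(np.mean(record.rp_tmin <= tc))


def _ols_with_p(
    y: np.ndarray, X: np.ndarray
) -> Optional[tuple[np.ndarray, float, float]]:
    """OLS of y on X (first column intercept); (coefs, p, log-p for X[:,1]).

    Returns None when the design is rank deficient.  The p-value is the
    two-sided t-test with n - k degrees of freedom and residual-estimated
    error variance.  The log p-value is carried alongside because for very
    strong effects p underflows to 0.0 and candidate ordering would be lost;
    a perfect (zero-residual) fit gets log-p of -inf.
    """
    n, k = X.shape
    if n <= k:
        return None
    if np.linalg.matrix_rank(X) < k:
        return None
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - k
    s2 = float(resid @ resid) / df
    # numerically exact fit: the t statistic is 0/0 noise, so decide from
    # whether the X[:,1] term contributes to the fitted values at all
    y_scale = max(1.0, float(np.sqrt(np.mean(y**2))))
    if s2 <= (1e-9 * y_scale) ** 2:
        contribution = abs(beta[1]) * float(np.std(X[:, 1]))
        if contribution <= 1e-9 * y_scale:
            return beta, 1.0, 0.0
        return beta, 0.0, -np.inf
    tstat = beta[1] / float(np.sqrt(s2 * np.linalg.inv(XtX)[1, 1]))
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    logp = float(np.log(2.0) + stats.t.logsf(abs(tstat), df))
    return beta, p, logp


def fit_yield_regression(
    records: Sequence[SeasonRecord], tc: float
) -> Optional[tuple[float, float, float, float]]:
    """Fit YF on (P(tc), R) with intercept; (b0, b1, b2, p_b1) or None.

    None signals an unfittable design at this candidate (for example P
    constant across seasons); callers exclude such candidates from the scan.
    """
    if len(records) < 4:
        raise ValueError("need at least 4 seasons (df = N - 3 >= 1)")
    y = np.array([rec.yf for rec in records])
    P = np.array([percent_cold_days(rec, tc) for rec in records])
    R = np.array([rec.r for rec in records])
    X = np.column_stack([np.ones(len(records)), P, R])
    out = _ols_with_p(y, X)
    if out is None:
        return None
    beta, p, _ = out
    return float(beta[0]), float(beta[1]), float(beta[2]), p


def scan_thresholds(
    records: Sequence[SeasonRecord],
    grid_lo: float = 0.0,
    grid_hi: float = 19.0,
    step: float = 0.1,
) -> ThresholdScan:
    """Fit the yield regression at every grid candidate (endpoints included)."""
    if len(records) < 4:
        raise ValueError("need at least 4 seasons for the scan")
    if step <= 0:
        raise ValueError("step must be > 0")
    if grid_hi < grid_lo:
        raise ValueError("grid_hi must be >= grid_lo")
    n_steps = int(round((grid_hi - grid_lo) / step))
    grid = np.round(grid_lo + step * np.arange(n_steps + 1), 10)

    y = np.array([rec.yf for rec in records])
    R = np.array([rec.r for rec in records])
    sorted_tmin = [np.sort(rec.rp_tmin) for rec in records]
    ndays = np.array([rec.rp_days for rec in records], dtype=float)
    # cold-day percentages for all candidates at once
    Pmat = np.column_stack(
        [
            100.0 * np.searchsorted(srt, grid, side="right") / nd
            for srt, nd in zip(sorted_tmin, ndays)
        ]
    )  # shape (n_grid, n_records)

    beta1 = np.full(grid.shape, np.nan)
    p_val = np.full(grid.shape, np.nan)
    log_p = np.full(grid.shape, np.nan)
    fittable = np.zeros(grid.shape, dtype=bool)
    for j in range(len(grid)):
        X = np.column_stack([np.ones(len(records)), Pmat[j], R])
        out = _ols_with_p(y, X)
        if out is None:
            continue
        b, p, lp = out
        beta1[j] = b[1]
        p_val[j] = p
        log_p[j] = lp
        fittable[j] = True
    return ThresholdScan(
        grid=grid, beta1=beta1, p_value=p_val, log_p=log_p, fittable=fittable
    )


def select_threshold(
    scan: ThresholdScan, pooled_rp_tmin: np.ndarray
) -> ThresholdResult:
    """Minimum-p selection with the warm-tie rule and detection criteria.

    Among fittable candidates, picks the smallest p-value for b1 (compared
    on the log scale so that underflowed p-values keep their ordering);
    candidates whose (log) p-values agree within 1e-12 are resolved to the
    largest T_C.
    Detection requires p < 0.05 and q1 <= T_C <= q3 where q1/q3 are the
    quartiles (linear interpolation) of the pooled RP minima.
    """
    pooled = np.asarray(pooled_rp_tmin, dtype=float)
    if scan.n_fittable == 0:
        return ThresholdResult(detected=False)
    q1, q3 = np.quantile(pooled, [0.25, 0.75])
    idx = np.flatnonzero(scan.fittable)
    # order candidates on log-p (finite even where p underflows to 0.0)
    lp = scan.log_p[idx]
    lp_min = np.min(lp)
    if np.isneginf(lp_min):
        tied = idx[np.isneginf(lp)]
    else:
        tied = idx[
            np.abs(lp - lp_min) <= P_TIE_TOL * max(1.0, abs(lp_min))
        ]
    j = tied[np.argmax(scan.grid[tied])]
    tc = float(scan.grid[j])
    p = float(scan.p_value[j])
    detected = bool(p < 0.05 and q1 <= tc <= q3)
    return ThresholdResult(
        detected=detected,
        tc=tc if detected else None,
        beta1=float(scan.beta1[j]),
        p_beta1=p,
        q1=float(q1),
        q3=float(q3),
    )


def quantify_effect(
    records: Sequence[SeasonRecord], result: ThresholdResult
) -> EffectReport:
    """Refit at the selected threshold and interpret b1 as kg/ha per 1% P."""
    if not result.detected or result.tc is None:
        raise ValueError("effect quantification requires a detected threshold")
    fit = fit_yield_regression(records, result.tc)
    if fit is None:
        raise ValueError("design became unfittable at the selected threshold")
    b0, b1, b2, p = fit
    return EffectReport(
        tc=result.tc,
        beta0=b0,
        beta1=b1,
        beta2=b2,
        p_beta1=p,
        yield_loss_expected=b1 < 0,
    )


def detect_threshold(
    records: Sequence[SeasonRecord],
    grid_lo: float = 0.0,
    grid_hi: float = 19.0,
    step: float = 0.1,
) -> ThresholdResult:
    """Scan, select and quantify in one call (the three-step procedure)."""
    scan = scan_thresholds(records, grid_lo=grid_lo, grid_hi=grid_hi, step=step)
    pooled = np.concatenate([rec.rp_tmin for rec in records])
    result = select_threshold(scan, pooled)
    if result.detected:
        eff = quantify_effect(records, result)
        result.beta0, result.beta1, result.beta2 = eff.beta0, eff.beta1, eff.beta2
        result.p_beta1 = eff.p_beta1
    return result


def spatial_threshold_regression(
    site_results: Sequence[tuple[float, float, float]],
) -> GeoRegression:
    """OLS of detected T_C on latitude and longitude across sites.

    ``site_results`` is a sequence of (latitude, longitude, tc) triples from
    sites with a detection.
    """
    import statsmodels.api as sm

    if len(site_results) < 3:
        raise ValueError("need at least 3 sites with a detected threshold")
    arr = np.asarray(site_results, dtype=float)
    X = sm.add_constant(arr[:, :2])
    model = sm.OLS(arr[:, 2], X).fit()
    return GeoRegression(
        intercept=float(model.params[0]),
        lat_coef=float(model.params[1]),
        lon_coef=float(model.params[2]),
        p_intercept=float(model.pvalues[0]),
        p_lat=float(model.pvalues[1]),
        p_lon=float(model.pvalues[2]),
        n_sites=len(site_results),
    )
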