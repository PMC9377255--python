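"""Reactivation-rate fitting and rate/abundance association.

The fecal-lysate assay tracks MPAG disappearance; each replicate's
concentration-vs-time trace is fit by ordinary least squares and the
reactivation rate is the magnitude of the (negative) slope in nM/s.
Replicate rates are averaged (mean +/- SEM) and log2-transformed.  The
purified-enzyme assay instead tracks product formation; its initial rate
is taken from the best-fitting contiguous window of the trace and divided
by enzyme concentration to give specific activity in 1/s.

Associations between rates and abundance predictors use the Wald slope
test: OLS slope divided by its standard error, referred to the standard
normal by default (a t(n-2) reference is available, matching common
graphing software).
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import AssociationResult, RateEstimate


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, r^2 of y on t."""
    tm, ym = t.mean(), y.mean()
    stt = np.sum((t - tm) ** 2)
    if stt == 0:
        raise ValueError("zero time variance")
    slope = np.sum((t - tm) * (y - ym)) / stt
    intercept = ym - slope * tm
    ss_tot = np.sum((y - ym) ** 2)
    ss_res = np.sum((y - intercept - slope * t) ** 2)
    # A constant trace explains nothing: r^2 = 0, so flat windows never
    # outcompete a genuine linear phase in window selection.
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(r2)


def fit_rate(timecourse: pd.DataFrame, sample_id: str | None = None) -> RateEstimate:
    """Per-replicate OLS fits of MPAG concentration on time, pooled.

    Expects columns ``replicate``, ``time_s``, ``mpag_nM`` (one sample).
    Rate = |slope| under the declining-MPAG convention; a rising trace is
    flagged and contributes rate 0.  SEM = sd / sqrt(k) over replicates;
    log2 is of the mean rate (None when the mean is 0).
    """
    sid = sample_id or (
        str(timecourse["sample_id"].iloc[0]) if "sample_id" in timecourse else "sample"
    )
    rates = []
    r2s = []
    rising = False
    for rep, sub in timecourse.groupby("replicate"):
        t = sub["time_s"].to_numpy(dtype=float)
        y = sub["mpag_nM"].to_numpy(dtype=float)
        if np.unique(t).size < 2:
            raise ValueError(f"replicate {rep}: fewer than 2 distinct time points")
        slope, _, r2 = _ols_line(t, y)
        if slope > 0:
            rising = True
            rates.append(0.0)
        else:
            rates.append(-slope)
        r2s.append(r2)
    rates_arr = np.asarray(rates)
    mean = float(rates_arr.mean())
    sem = float(rates_arr.std(ddof=1) / np.sqrt(len(rates))) if len(rates) > 1 else 0.0
    return RateEstimate(
        id=sid,
        replicate_rates=tuple(float(r) for r in rates),
        mean_rate=mean,
        sem=sem,
        log2_rate=float(np.log2(mean)) if mean > 0 else None,
        r_squared=float(np.mean(r2s)),
        flagged_rising=rising,
    )


def fit_rates(timecourses: pd.DataFrame) -> list[RateEstimate]:
    """fit_rate per sample of a long-format time-course table."""
    return [
        fit_rate(sub, str(sid)) for sid, sub in timecourses.groupby("sample_id")
    ]


def specific_activity(
    times_s: Sequence[float],
    product_nM: Sequence[float],
    enzyme_conc_nM: float,
    min_window_frac: float = 0.25,
    r2_floor: float = 0.90,
) -> dict:
    """Initial-rate specific activity (1/s) from a product-formation trace.

    The initial rate is the slope of the best contiguous window of at
    least ``max(3, min_window_frac * n)`` points that maximizes r^2
    (ties: longer window, then earlier start), divided by the enzyme
    concentration.  Raises when no window reaches ``r2_floor`` ("no
    linear phase").
    """
    if enzyme_conc_nM <= 0:
        raise ValueError("enzyme concentration must be positive")
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(product_nM, dtype=float)
    if t.size != y.size or t.size < 3:
        raise ValueError("need >= 3 matched (time, product) points")
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    n = t.size
    min_len = max(3, int(np.ceil(min_window_frac * n)))
    best = None  # (r2, length, -start, slope)
    for start in range(0, n - min_len + 1):
        for end in range(start + min_len, n + 1):
            tw, yw = t[start:end], y[start:end]
            if np.unique(tw).size < 2:
                continue
            slope, _, r2 = _ols_line(tw, yw)
            key = (round(r2, 12), end - start, -start)
            if best is None or key > best[0]:
                best = (key, slope, (start, end))
    if best is None or best[0][0] < r2_floor:
        raise ValueError("no linear phase: no window reaches the r^2 floor")
    slope = best[1]
    start, end = best[2]
    return {
        "specific_activity_per_s": slope / enzyme_conc_nM,
        "initial_rate_nM_per_s": slope,
        "window": (int(start), int(end)),
        "r_squared": float(best[0][0]),
    }


def wald_slope_test(
    x: Sequence[float],
    y: Sequence[float],
    predictor: str = "predictor",
    reference: str = "normal",
) -> AssociationResult:
    """Wald test for a non-zero OLS slope of y on x.

    ``reference`` "normal" refers slope/se to N(0,1); "t" uses t(n-2).
    A perfect linear fit has se 0; the result is flagged ``exact_fit``
    with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    if reference not in ("normal", "t"):
        raise ValueError(f"unknown reference {reference!r}")
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    s2 = np.sum(resid**2) / (n - 2)
    se = np.sqrt(s2 / sxx)
    if se == 0:
        return AssociationResult(predictor, float(slope), 0.0,
                                 np.inf if slope != 0 else 0.0,
                                 0.0 if slope != 0 else 1.0,
                                 int(n), reference, exact_fit=True)
    z = slope / se
    if reference == "normal":
        p = 2 * stats.norm.sf(abs(z))
    else:
        p = 2 * stats.t.sf(abs(z), n - 2)
    return AssociationResult(predictor, float(slope), float(se), float(z),
                             float(p), int(n), reference)


def associate_rates(
    rates: Sequence[RateEstimate],
    predictors: Mapping[str, pd.Series | Mapping[str, float]],
    reference: str = "normal",
    use_log2_rate: bool = True,
    min_shared: int = 3,
) -> pd.DataFrame:
    """One Wald slope test of rate against each named predictor.

    ``predictors`` maps a name (total GUS, a class, a taxon...) to a
    per-sample series; samples missing from either side are dropped, and
    predictors sharing fewer than ``min_shared`` samples with the rates
    are skipped.  No multiplicity adjustment is applied; a
    Benjamini-Hochberg column can be added downstream when scanning many
    taxa.
    """
    rate_by_id = {}
    for r in rates:
        val = r.log2_rate if use_log2_rate else r.mean_rate
        if val is not None:
            rate_by_id[r.id] = val
    rows = []
    for name, series in predictors.items():
        s = pd.Series(dict(series), dtype=float).dropna()
        shared = sorted(set(s.index) & set(rate_by_id))
        if len(shared) < min_shared:
            continue
        x = s[shared].to_numpy()
        if np.ptp(x) == 0:
            continue
        y = np.array([rate_by_id[k] for k in shared])
        res = wald_slope_test(x, y, predictor=name, reference=reference)
        rows.append(
            {
                "predictor": name,
                "slope": res.slope,
                "slope_se": res.slope_se,
                "statistic": res.statistic,
                "p": res.p_value,
                "n": res.n,
                "reference": res.reference,
            }
        )
    return pd.DataFrame(
        rows, columns=["predictor", "slope", "slope_se", "statistic", "p", "n",
                       "reference"],
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out
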