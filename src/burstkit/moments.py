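"""Bootstrap moment summaries and log-log scaling regressions.

The diagnostics here discriminate constant-rate (Poisson) transcription from
bursty transcription: under Poisson production, variance scales linearly with
mean (log-log slope 1) and CV falls as 1/sqrt(mean) (slope -1/2), whereas
promoter switching produces a power law with variance slope between 1 and 2
and a mean-independent CV.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class MomentSummary:
    """Descriptive statistics of one clone's expression distribution with
    percentile-bootstrap 95% confidence intervals."""

    clone_id: str
    n: int
    mean: float
    variance: float
    cv: float
    fano: float
    mean_ci: tuple[float, float]
    variance_ci: tuple[float, float]
    cv_ci: tuple[float, float]
    fano_ci: tuple[float, float]
    degenerate: bool = False  # all-zero input: CV/Fano undefined

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("mean_ci", "variance_ci", "cv_ci", "fano_ci"):
            lo, hi = d.pop(k)
            d[k + "_lo"], d[k + "_hi"] = lo, hi
        return d


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_se: float
    slope_ci: tuple[float, float]
    r2: float
    spearman_rs: float
    p_slope: float
    p_spearman: float
    n: int

    def to_dict(self) -> dict:
        d = asdict(self)
        lo, hi = d.pop("slope_ci")
        d["slope_ci_lo"], d["slope_ci_hi"] = lo, hi
        return d


def _point_stats(v: np.ndarray) -> tuple[float, float, float, float]:
    m = v.mean()
    var = v.var(ddof=1)
    if m == 0:
        return m, var, np.nan, np.nan
    return m, var, np.sqrt(var) / m, var / m


def bootstrap_moments(
    values: np.ndarray, B: int = 1000, seed: int = 0, clone_id: str = ""
) -> MomentSummary:
    """Mean/variance/CV/Fano with 95% CIs from the 2.5% and 97.5% quantiles
    of B with-replacement resamples."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 observations")
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    mean, var, cv, fano = _point_stats(v)
    idx = rng.integers(0, v.size, size=(B, v.size))
    res = v[idx]
    bm = res.mean(axis=1)
    bv = res.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bcv = np.where(bm > 0, np.sqrt(bv) / bm, np.nan)
        bf = np.where(bm > 0, bv / bm, np.nan)

    def ci(a: np.ndarray) -> tuple[float, float]:
        a = a[np.isfinite(a)]
        if a.size == 0:
            return (np.nan, np.nan)
        return (float(np.quantile(a, 0.025)), float(np.quantile(a, 0.975)))

    return MomentSummary(
        clone_id=clone_id,
        n=int(v.size),
        mean=float(mean),
        variance=float(var),
        cv=float(cv),
        fano=float(fano),
        mean_ci=ci(bm),
        variance_ci=ci(bv),
        cv_ci=ci(bcv),
        fano_ci=ci(bf),
        degenerate=bool(mean == 0),
    )


def summarize_counts(distributions, B: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Batch bootstrap_moments over CountDistribution objects -> tidy frame."""
    dists = list(distributions)
    children = np.random.SeedSequence(seed).spawn(len(dists))
    rows = [
        bootstrap_moments(d.counts, B=B, seed=child, clone_id=d.clone_id).to_dict()
        for d, child in zip(dists, children)
    ]
    return pd.DataFrame(rows)


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    rs, p = stats.spearmanr(x, y)
    if x.size < 10 and np.isfinite(rs):
        # exact permutation p-value at small n, where the t-approximation
        # is unreliable; Pearson on ranks over all n! pairings, vectorized
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        perms = np.array(list(itertools.permutations(rx)))
        pc = perms - perms.mean(axis=1, keepdims=True)
        yc = ry - ry.mean()
        denom = np.sqrt((pc**2).sum(axis=1) * (yc**2).sum())
        all_rs = (pc @ yc) / denom
        p = float(np.mean(np.abs(all_rs) >= abs(rs) - 1e-12))
    return float(rs), float(p)


def loglog_regression(x, y) -> RegressionResult:
    """OLS of log10(y) on log10(x); Spearman rank correlation on raw values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    bad = np.flatnonzero((x <= 0) | (y <= 0) | ~np.isfinite(x) | ~np.isfinite(y))
    if bad.size:
        raise ValueError(f"non-positive or non-finite values at indices {bad.tolist()}")
    lx, ly = np.log10(x), np.log10(y)
    if np.allclose(lx, lx[0]):
        raise ValueError("x has zero variance on the log scale")
    if np.allclose(ly, ly[0]):
        # flat response: slope 0 and no variance explained, by convention
        return RegressionResult(
            slope=0.0,
            intercept=float(ly[0]),
            slope_se=0.0,
            slope_ci=(0.0, 0.0),
            r2=0.0,
            spearman_rs=0.0,
            p_spearman=1.0,
            p_slope=1.0,
            n=int(x.size),
        )
    model = sm.OLS(ly, sm.add_constant(lx)).fit()
    ci = model.conf_int(alpha=0.05)
    rs, p_rs = _spearman(x, y)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        r2=float(model.rsquared),
        spearman_rs=rs,
        p_slope=float(model.pvalues[1]),
        p_spearman=p_rs,
        n=int(x.size),
    )


def slope_test(result: RegressionResult, null_slope: float) -> float:
    """Two-sided t-test of the fitted slope against ``null_slope``."""
    if result.n < 3:
        raise ValueError("need residual degrees of freedom >= 1")
    if result.slope == null_slope:
        return 1.0
    if result.slope_se <= 1e-10 * max(1.0, abs(result.slope)):
        raise ValueError("degenerate fit: zero residual variance")
    t = (result.slope - null_slope) / result.slope_se
    df = result.n - 2
    return float(2.0 * stats.t.sf(abs(t), df))


def compare_regressions_ftest(subset: tuple, full: tuple) -> float:
    """Nested-model F-test for whether a subset shows a different log-log
    trend than the full set: pooled OLS with group indicator and
    group x log10(x) interaction vs pooled OLS without them."""
    xs, ys = (np.asarray(a, dtype=float) for a in subset)
    xf, yf = (np.asarray(a, dtype=float) for a in full)
    for x, y in ((xs, ys), (xf, yf)):
        if np.any(x <= 0) or np.any(y <= 0) or x.size < 3:
            raise ValueError("both datasets must be valid for loglog_regression")
    if xs.size == xf.size and np.array_equal(np.sort(xs), np.sort(xf)) and np.array_equal(
        np.sort(ys), np.sort(yf)
    ):
        return 1.0
    lx = np.log10(np.concatenate([xs, xf]))
    ly = np.log10(np.concatenate([ys, yf]))
    grp = np.concatenate([np.ones(xs.size), np.zeros(xf.size)])
    X_full = np.column_stack([np.ones_like(lx), lx, grp, grp * lx])
    X_red = X_full[:, :2]
    fit_full = sm.OLS(ly, X_full).fit()
    fit_red = sm.OLS(ly, X_red).fit()
    f = fit_full.compare_f_test(fit_red)
    return float(f[1])


def poisson_reference(means) -> dict:
    """Variance and CV expected under constant-rate (Poisson) transcription."""
    m = np.asarray(means, dtype=float)
    if np.any(m <= 0):
        raise ValueError("means must be positive")
    return {"variance": m.copy(), "cv": 1.0 / np.sqrt(m)}
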