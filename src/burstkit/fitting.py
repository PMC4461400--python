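"""Maximum-likelihood burst-parameter inference from mRNA count distributions.

Each clone's per-cell counts are modeled as iid draws from the stationary
telegraph law.  With the degradation rate δ fixed (δ = 1 defines the time
unit) and the transcription rate λ = k_m/δ assumed shared across clones, the
effective free parameters are the burst frequency f = k_on/δ and the burst
size b = k_m/k_off, i.e. α = f and β = λ/b in the beta-Poisson law.  The fit
minimizes the negative log-likelihood over (log10 b, log10 f); 95% confidence
intervals come from the profile likelihood at a 1.92 log-likelihood-ratio
offset (half the 0.95 quantile of χ² with 1 df).

δ enters only through the normalization of f: the counts are stationary, so
rescaling δ rescales the reported f (units) without changing the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .telegraph import CountDistribution, beta_poisson_logpmf
from .moments import RegressionResult, loglog_regression

LOG10_B_BOUNDS = (-2.0, 4.0)
LOG10_F_BOUNDS = (-3.0, 3.0)
_BOUNDARY_EPS = 1e-3
_LOGP_FLOOR = -745.0  # smallest log representable in double precision
_N_STARTS = 5
_NLL_TOL = 1e-8
PROFILE_LLR_OFFSET_95 = float(stats.chi2.ppf(0.95, df=1) / 2.0)  # = 1.92


class FitError(RuntimeError):
    pass


@dataclass
class FitResult:
    clone_id: str
    burst_size: float
    burst_freq: float
    lam: float
    delta: float
    nll: float
    converged: bool
    boundary: bool
    n_cells: int
    burst_size_ci: tuple[float, float] | None = None
    burst_freq_ci: tuple[float, float] | None = None
    ci_open_ended: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("burst_size_ci", "burst_freq_ci"):
            ci = d.pop(key)
            d[key + "_lo"] = ci[0] if ci else np.nan
            d[key + "_hi"] = ci[1] if ci else np.nan
        return d


class _Likelihood:
    """NLL over unique counts with a memo keyed by rounded (b, f)."""

    def __init__(self, counts: np.ndarray, lam: float):
        self.values, self.weights = np.unique(counts, return_counts=True)
        self.lam = float(lam)
        self.n = int(counts.size)
        self._cache: dict[tuple[float, float], float] = {}

    def nll(self, b: float, f: float) -> float:
        key = (round(b, 10), round(f, 10))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        logp = beta_poisson_logpmf(self.values, alpha=f, beta=self.lam / b, lam=self.lam)
        logp = np.maximum(logp, _LOGP_FLOOR)
        val = float(-np.dot(self.weights, logp))
        self._cache[key] = val
        return val

    def nll_log10(self, theta: np.ndarray) -> float:
        return self.nll(10.0 ** theta[0], 10.0 ** theta[1])


def neg_log_likelihood(
    b: float, f: float, lam: float, counts: CountDistribution | np.ndarray
) -> float:
    """-Σ_cells log p(n_cell | α = f, β = λ/b, λ); additive over cells."""
    if b <= 0 or f <= 0 or lam <= 0:
        raise ValueError("b, f and lam must be positive")
    arr = counts.counts if isinstance(counts, CountDistribution) else np.asarray(counts)
    return _Likelihood(arr, lam).nll(b, f)


def _moment_start(counts: np.ndarray, lam: float) -> np.ndarray:
    """Method-of-moments initialization in the bursty regime:
    Fano ≈ 1 + b, mean ≈ f·b."""
    counts = np.sort(counts)  # fixed summation order: cell order irrelevant
    m = counts.mean()
    v = counts.var(ddof=1) if counts.size > 1 else m
    fano = v / m if m > 0 else 1.0
    b0 = max(fano - 1.0, 0.05)
    f0 = max(m / b0, 1e-3) if m > 0 else 1e-3
    theta = np.array([np.log10(b0), np.log10(f0)])
    theta[0] = np.clip(theta[0], *LOG10_B_BOUNDS)
    theta[1] = np.clip(theta[1], *LOG10_F_BOUNDS)
    return theta


def fit_clone(
    counts: CountDistribution,
    delta: float = 1.0,
    lam: float = 1000.0,
    seed: int = 0,
    compute_ci: bool = False,
) -> FitResult:
    """MLE of (burst size, burst frequency) for one clone.

    Multi-start Nelder–Mead in (log10 b, log10 f) from the method-of-moments
    point plus jittered restarts.  ``compute_ci`` adds 95% profile-likelihood
    intervals (see :func:`profile_ci`).
    """
    arr = counts.counts
    if arr.size < 30:
        warnings.warn(
            f"clone {counts.clone_id}: only {arr.size} cells; estimates may be unstable",
            stacklevel=2,
        )
    if delta <= 0 or lam <= 0:
        raise ValueError("delta and lam must be positive")
    if np.all(arr == 0):
        return FitResult(
            clone_id=counts.clone_id,
            burst_size=10.0 ** LOG10_B_BOUNDS[0],
            burst_freq=10.0 ** LOG10_F_BOUNDS[0],
            lam=lam,
            delta=delta,
            nll=0.0,
            converged=False,
            boundary=True,
            n_cells=int(arr.size),
        )

    lik = _Likelihood(arr, lam)
    rng = np.random.default_rng(seed)
    start0 = _moment_start(arr, lam)
    starts = [start0] + [
        np.clip(
            start0 + rng.normal(0.0, 0.35, size=2),
            [LOG10_B_BOUNDS[0], LOG10_F_BOUNDS[0]],
            [LOG10_B_BOUNDS[1], LOG10_F_BOUNDS[1]],
        )
        for _ in range(_N_STARTS - 1)
    ]
    bounds = [LOG10_B_BOUNDS, LOG10_F_BOUNDS]
    best = None
    for theta0 in starts:
        res = optimize.minimize(
            lik.nll_log10,
            theta0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-6, "fatol": _NLL_TOL, "maxiter": 600},
        )
        if best is None or res.fun < best.fun:
            best = res
    start_nlls = [lik.nll_log10(t) for t in starts]
    converged = bool(best.success) and best.fun <= min(start_nlls) + _NLL_TOL
    theta = best.x
    boundary = bool(
        min(theta[0] - LOG10_B_BOUNDS[0], LOG10_B_BOUNDS[1] - theta[0]) < _BOUNDARY_EPS
        or min(theta[1] - LOG10_F_BOUNDS[0], LOG10_F_BOUNDS[1] - theta[1]) < _BOUNDARY_EPS
    )
    fit = FitResult(
        clone_id=counts.clone_id,
        burst_size=float(10.0 ** theta[0]),
        burst_freq=float(10.0 ** theta[1]),
        lam=float(lam),
        delta=float(delta),
        nll=float(best.fun),
        converged=converged,
        boundary=boundary,
        n_cells=int(arr.size),
    )
    if compute_ci:
        profile_ci(fit, counts, _likelihood=lik)
    return fit


def _profile_value(lik: _Likelihood, which: str, log10_val: float) -> float:
    """NLL minimized over the other parameter at a fixed profile point."""
    other_bounds = LOG10_F_BOUNDS if which == "b" else LOG10_B_BOUNDS

    def obj(other: float) -> float:
        if which == "b":
            return lik.nll(10.0 ** log10_val, 10.0 ** other)
        return lik.nll(10.0 ** other, 10.0 ** log10_val)

    res = optimize.minimize_scalar(
        obj, bounds=other_bounds, method="bounded", options={"xatol": 1e-6}
    )
    return float(res.fun)


def _ci_endpoint(
    lik: _Likelihood,
    which: str,
    mle_log10: float,
    target: float,
    direction: int,
    hard_bound: float,
    tol: float = 1e-3,
) -> tuple[float, bool]:
    """Bisection for the profile point where NLL - NLL_opt = offset.

    Returns (log10 endpoint, open_ended).  Bracket grows geometrically
    (factor 2 in log10 steps) toward ``hard_bound``.
    """
    step = 0.1
    lo = mle_log10
    hi = mle_log10 + direction * step
    while True:
        hi = np.clip(hi, min(mle_log10, hard_bound), max(mle_log10, hard_bound))
        if _profile_value(lik, which, hi) >= target:
            break
        if hi == hard_bound:
            return float(hard_bound), True
        lo = hi
        step *= 2.0
        hi = mle_log10 + direction * step
    # bisection on [lo, hi]
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        g = _profile_value(lik, which, mid) - target
        if abs(g) < tol:
            return float(mid), False
        if g > 0:
            hi = mid
        else:
            lo = mid
        if abs(hi - lo) < 1e-10:
            return float(mid), False
    return float(0.5 * (lo + hi)), False  # pragma: no cover


def profile_ci(
    fit: FitResult,
    counts: CountDistribution,
    llr_offset: float = PROFILE_LLR_OFFSET_95,
    _likelihood: _Likelihood | None = None,
) -> FitResult:
    """95% profile-likelihood CIs for burst size and burst frequency.

    Endpoints satisfy |profile NLL - optimal NLL - llr_offset| < 1e-3 unless
    the offset is not reached inside the optimization bounds, in which case
    the interval is truncated there and flagged open-ended.
    """
    if not fit.converged:
        raise FitError("profile CIs require a converged fit")
    lik = _likelihood or _Likelihood(counts.counts, fit.lam)
    target = fit.nll + llr_offset
    open_ended = False
    cis = {}
    for which, mle, bounds in (
        ("b", np.log10(fit.burst_size), LOG10_B_BOUNDS),
        ("f", np.log10(fit.burst_freq), LOG10_F_BOUNDS),
    ):
        lo, open_lo = _ci_endpoint(lik, which, mle, target, -1, bounds[0])
        hi, open_hi = _ci_endpoint(lik, which, mle, target, +1, bounds[1])
        open_ended |= open_lo or open_hi
        cis[which] = (10.0 ** lo, 10.0 ** hi)
    fit.burst_size_ci = cis["b"]
    fit.burst_freq_ci = cis["f"]
    fit.ci_open_ended = open_ended
    return fit


@dataclass
class CohortFitResult:
    table: pd.DataFrame
    regressions: dict[str, RegressionResult]
    failures: list[str]


def fit_cohort(
    distributions,
    delta: float = 1.0,
    lam: float = 1000.0,
    seed: int = 0,
    compute_ci: bool = False,
    truth: pd.DataFrame | None = None,
) -> CohortFitResult:
    """Fit every clone and emit the four cross-correlation regressions
    (RNA mean and CV against fitted burst size and burst frequency)."""
    dists = list(distributions)
    if not dists:
        raise ValueError("need at least one clone")
    rows, failures = [], []
    for i, d in enumerate(dists):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_clone(d, delta=delta, lam=lam, seed=seed + i, compute_ci=compute_ci)
            row = fit.to_dict()
        except Exception as exc:  # noqa: BLE001 - batch keeps going, failure recorded
            failures.append(f"{d.clone_id}: {exc}")
            continue
        m = d.counts.mean()
        v = d.counts.var(ddof=1)
        row["mean"] = m
        row["variance"] = v
        row["cv"] = np.sqrt(v) / m if m > 0 else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    if truth is not None:
        table = table.merge(truth, on="clone_id", how="left", suffixes=("", "_true"))

    regressions: dict[str, RegressionResult] = {}
    ok = table[(table["mean"] > 0) & np.isfinite(table["cv"]) & (table["cv"] > 0)]
    if len(ok) >= 3:
        for yname, xname, key in (
            ("mean", "burst_size", "mean_vs_burst_size"),
            ("mean", "burst_freq", "mean_vs_burst_freq"),
            ("cv", "burst_size", "cv_vs_burst_size"),
            ("cv", "burst_freq", "cv_vs_burst_freq"),
        ):
            regressions[key] = loglog_regression(ok[xname], ok[yname])
    return CohortFitResult(table=table, regressions=regressions, failures=failures)


# ---------------------------------------------------------------------------
# RNA degradation rate from an inhibition time course
# ---------------------------------------------------------------------------


@dataclass
class DecayFit:
    delta: float
    half_life: float
    slope_se: float
    r2: float
    n_timepoints: int
    nondecaying: bool  # fitted rate <= 0 (half-life undefined)


def estimate_degradation_rate(timecourse: pd.DataFrame, series: str = "treated") -> DecayFit:
    """First-order decay rate from a transcription-inhibition qPCR course.

    Expects tidy columns ``series`` (treated/untreated), ``gene``
    (target/reference), ``time``, ``replicate``, ``Ct``.  Per timepoint the
    target abundance relative to the reference is 2^-(Ct_target - Ct_ref),
    normalized to t = 0; δ is minus the OLS slope of its natural log vs time.
    """
    required = {"series", "gene", "time", "Ct"}
    if not required.issubset(timecourse.columns):
        raise ValueError(f"timecourse must have columns {sorted(required)}")
    sub = timecourse[timecourse["series"] == series]
    if sub.empty:
        raise ValueError(f"no rows for series {series!r}")
    ct = sub.groupby(["time", "gene"])["Ct"].mean().unstack("gene")
    if "target" not in ct.columns or "reference" not in ct.columns:
        raise ValueError("need both 'target' and 'reference' genes")
    if len(ct) < 3 or 0.0 not in ct.index:
        raise ValueError("need >= 3 timepoints including t = 0")
    dct = ct["target"] - ct["reference"]
    log_abund = -np.log(2.0) * (dct - dct.loc[0.0])
    t = ct.index.to_numpy(dtype=float)
    slope, intercept, r, p, se = stats.linregress(t, log_abund.to_numpy())
    delta = -float(slope)
    return DecayFit(
        delta=delta,
        half_life=float(np.log(2.0) / delta) if delta > 0 else np.nan,
        slope_se=float(se),
        r2=float(r**2),
        n_timepoints=int(len(ct)),
        nondecaying=bool(delta <= 0),
    )


def write_fits_tsv(result: CohortFitResult, path) -> None:
    result.table.to_csv(path, sep="\t", index=False)


def read_fits_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
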