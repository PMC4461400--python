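"""Two-state (telegraph) model of transcription.

A promoter switches between a silent Off state and a productive On state
(rates ``k_on``, ``k_off``); mRNA is synthesised at rate ``k_m`` while On and
degrades first-order at rate ``delta``.  The stationary mRNA copy-number law
is the Peccoud–Ycart distribution, i.e. a beta-Poisson mixture::

    p(n) = ∫₀¹ Poisson(n; λ x) Beta(x; α, β) dx

with ``alpha = k_on/delta``, ``beta = k_off/delta`` and ``lam = k_m/delta``.
This module provides the analytic PMF and moments, stationary sampling, and
an exact stochastic-simulation (Gillespie) oracle, optionally extended with a
translation stage that emulates a long-lived fluorescent-protein reporter.

Numerics
--------
The PMF is evaluated through the confluent-hypergeometric closed form

    p(n) = λⁿ/n! · B(α+n, β)/B(α, β) · ₁F₁(α+n; α+β+n; −λ)

after a Kummer transformation, ₁F₁(α+n; α+β+n; −λ) =
e^{−λ} ₁F₁(β; α+β+n; λ), whose series has exclusively positive terms and is
summed in log space (no cancellation, no overflow).  A fixed-order
Gauss–Jacobi quadrature of the mixture integral is available as an
independent evaluation route (``method="quadrature"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from numba import njit
from scipy.special import betaln, gammaln, logsumexp, roots_jacobi
from scipy.stats import poisson


class InvalidParameterError(ValueError):
    """Raised for kinetic parameters outside the model's domain."""


class DegenerateDistributionError(ValueError):
    """Raised when a requested statistic is undefined (e.g. CV at mean 0)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TelegraphParams:
    """Kinetic rates of the two-state model, all per unit time.

    Derived, time-unit-invariant quantities:

    * ``alpha = k_on/delta``   — normalized On rate (burst frequency, f)
    * ``beta  = k_off/delta``
    * ``lam   = k_m/delta``
    * ``burst_size = k_m/k_off``  — mean transcripts per On episode (b)
    """

    k_on: float
    k_off: float
    k_m: float
    delta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_m", "delta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v}")
        if self.delta <= 0:
            raise InvalidParameterError("delta must be > 0")

    @property
    def alpha(self) -> float:
        return self.k_on / self.delta

    @property
    def beta(self) -> float:
        return self.k_off / self.delta

    @property
    def lam(self) -> float:
        return self.k_m / self.delta

    @property
    def burst_size(self) -> float:
        if self.k_off == 0:
            return np.inf
        return self.k_m / self.k_off

    @property
    def burst_freq(self) -> float:
        """Off→On rate in units of the mRNA degradation rate (f = k_on/δ)."""
        return self.k_on / self.delta

    @property
    def burst_period(self) -> float:
        """Reciprocal of the normalized On rate (mean wait between bursts)."""
        f = self.burst_freq
        return np.inf if f == 0 else 1.0 / f

    @classmethod
    def from_bursts(
        cls, burst_size: float, burst_freq: float, lam: float, delta: float = 1.0
    ) -> "TelegraphParams":
        """Build rates from (b, f, λ) with δ setting the time unit."""
        if burst_size <= 0 or burst_freq <= 0 or lam <= 0:
            raise InvalidParameterError("burst_size, burst_freq and lam must be > 0")
        return cls(
            k_on=burst_freq * delta,
            k_off=lam * delta / burst_size,
            k_m=lam * delta,
            delta=delta,
        )

    def to_dict(self) -> dict:
        return {
            "k_on": float(self.k_on),
            "k_off": float(self.k_off),
            "k_m": float(self.k_m),
            "delta": float(self.delta),
        }


@dataclass(frozen=True)
class Moments:
    mean: float
    variance: float
    cv: float
    fano: float


@dataclass
class CountDistribution:
    """Per-cell mRNA copy numbers for one clone."""

    clone_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.size < 1:
            raise ValueError("counts must contain at least one cell")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("counts must be integers")
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        self.counts = arr.astype(np.int64)

    def __len__(self) -> int:
        return int(self.counts.size)


# ---------------------------------------------------------------------------
# PMF evaluation
# ---------------------------------------------------------------------------

_N_CAP = 2_000_000  # hard truncation guard


def beta_poisson_logpmf(
    n: np.ndarray | Iterable[int],
    alpha: float,
    beta: float,
    lam: float,
    method: str = "series",
) -> np.ndarray:
    """log p(n) of the stationary telegraph law at arbitrary copy numbers.

    ``method="series"`` is the closed-form hypergeometric route (log-space
    positive-term series); ``method="quadrature"`` integrates the
    beta-Poisson mixture with Gauss–Jacobi nodes and is provided as an
    independent cross-check (it loses accuracy for beta ≳ 1e3).
    """
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    if np.any(n < 0):
        raise ValueError("copy numbers must be non-negative")
    if alpha < 0 or beta < 0 or lam < 0:
        raise InvalidParameterError("alpha, beta, lam must be >= 0")

    # Degenerate branches: permanently-On promoter is Poisson; no
    # transcription (or never-On promoter) puts all mass at zero.
    if lam == 0 or alpha == 0:
        return np.where(n == 0, 0.0, -np.inf)
    if beta == 0:
        return poisson.logpmf(n, lam)

    if method == "series":
        out = _logpmf_series(n, alpha, beta, lam)
        if not np.all(np.isfinite(out) | (out == -np.inf)):  # pragma: no cover
            out = _logpmf_quadrature(n, alpha, beta, lam)
        return out
    if method == "quadrature":
        return _logpmf_quadrature(n, alpha, beta, lam)
    raise ValueError(f"unknown method {method!r}")


def _logpmf_series(n: np.ndarray, alpha: float, beta: float, lam: float) -> np.ndarray:
    # Terms t_k(n) of 1F1(beta; alpha+beta+n; lam); ratio t_{k+1}/t_k <=
    # lam/(k+1), so K = lam + 12*sqrt(lam) + 40 bounds the tail far below
    # double precision.
    K = int(np.ceil(lam + 12.0 * np.sqrt(lam + 1.0) + 40.0))
    k = np.arange(K + 1)
    nmax = int(n.max())
    g = gammaln(alpha + beta + np.arange(nmax + K + 2))  # g[j] = lnΓ(α+β+j)
    ck = k * np.log(lam) - gammaln(k + 1.0) + gammaln(beta + k) - gammaln(beta)
    log_t = ck[:, None] - g[n[None, :] + k[:, None]] + g[n][None, :]
    log_1f1 = logsumexp(log_t, axis=0)
    return (
        n * np.log(lam)
        - gammaln(n + 1.0)
        + gammaln(alpha + n)
        - gammaln(alpha)
        + gammaln(alpha + beta)
        - g[n]
        - lam
        + log_1f1
    )


def _logpmf_quadrature(
    n: np.ndarray, alpha: float, beta: float, lam: float, order: int | None = None
) -> np.ndarray:
    if order is None:
        # e^{±λx} needs polynomial order ~ λ for geometric convergence.
        order = int(min(5000, max(100, 1.1 * lam + 15.0 * np.sqrt(lam) + 60.0)))
    t, w = roots_jacobi(order, beta - 1.0, alpha - 1.0)
    x = 0.5 * (t + 1.0)
    logw = np.log(w) + (1.0 - alpha - beta) * np.log(2.0) - betaln(alpha, beta)
    logpois = poisson.logpmf(n[:, None], lam * x[None, :])
    return logsumexp(logpois + logw[None, :], axis=1)


def stationary_pmf(
    params: TelegraphParams,
    tail_tol: float = 1e-10,
    min_support: int | None = None,
    method: str = "series",
) -> np.ndarray:
    """Stationary PMF over n = 0..N, truncated so omitted mass < ``tail_tol``.

    The returned vector is renormalized over the truncated support.
    ``min_support`` forces the support to extend at least that far (used by
    likelihood code so every observed count is covered).
    """
    if not (0 < tail_tol < 1):
        raise ValueError("tail_tol must be in (0, 1)")
    a, b, lam = params.alpha, params.beta, params.lam

    if lam == 0 or a == 0:
        n_top = max(0, (min_support or 0))
        pmf = np.zeros(n_top + 1)
        pmf[0] = 1.0
        return pmf

    m = analytic_moments(params, allow_zero_mean=True)
    sd = np.sqrt(m.variance)
    N = int(np.ceil(m.mean + 10.0 * sd + 25.0))
    if min_support is not None:
        N = max(N, int(min_support))
    while True:
        n = np.arange(N + 1)
        p = np.exp(beta_poisson_logpmf(n, a, b, lam, method=method))
        missing = 1.0 - p.sum()
        if missing < tail_tol or N >= _N_CAP:
            break
        N = min(_N_CAP, 2 * N + 50)
    return p / p.sum()


# ---------------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------------


def analytic_moments(
    params: TelegraphParams, allow_zero_mean: bool = False
) -> Moments:
    """Exact stationary mean/variance/CV/Fano.

    mean = λα/(α+β);  var = mean + λ²αβ / [(α+β)²(α+β+1)].
    """
    a, b, lam = params.alpha, params.beta, params.lam
    if a + b == 0:
        raise InvalidParameterError("k_on + k_off must be > 0")
    mean = lam * a / (a + b)
    variance = mean + lam**2 * a * b / ((a + b) ** 2 * (a + b + 1.0))
    if mean == 0:
        if not allow_zero_mean:
            raise DegenerateDistributionError("CV undefined at mean 0")
        return Moments(mean=0.0, variance=0.0, cv=np.nan, fano=np.nan)
    return Moments(
        mean=mean,
        variance=variance,
        cv=float(np.sqrt(variance) / mean),
        fano=float(variance / mean),
    )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def sample_stationary(
    params: TelegraphParams,
    n_cells: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    clone_id: str = "clone",
) -> CountDistribution:
    """Draw iid cells from the stationary law via x ~ Beta(α, β), n ~ Poisson(λx)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    a, b, lam = params.alpha, params.beta, params.lam
    if lam == 0 or a == 0:
        x = np.zeros(n_cells)
    elif b == 0:
        x = np.ones(n_cells)
    else:
        x = rng.beta(a, b, size=n_cells)
    counts = rng.poisson(lam * x)
    return CountDistribution(clone_id=clone_id, counts=counts)


# ---------------------------------------------------------------------------
# Gillespie stochastic-simulation oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinKinetics:
    """Translation stage: mRNA → mRNA + P at k_p·m, P → ∅ at delta_p·p."""

    k_p: float
    delta_p: float

    def __post_init__(self) -> None:
        if self.k_p < 0 or self.delta_p <= 0:
            raise InvalidParameterError("k_p >= 0 and delta_p > 0 required")


@dataclass
class GillespieResult:
    promoter_state: np.ndarray  # 0 = Off, 1 = On at t_end
    mrna: np.ndarray
    protein: np.ndarray | None
    on_fraction: np.ndarray  # fraction of [0, t_end] spent On, per replicate


@njit(cache=False)
def _ssa_core(kon, koff, km, delta, kp, dp, with_protein, t_end, n_rep, seed):
    np.random.seed(seed)
    state = np.empty(n_rep, dtype=np.int64)
    mrna = np.empty(n_rep, dtype=np.int64)
    prot = np.empty(n_rep, dtype=np.int64)
    onf = np.empty(n_rep, dtype=np.float64)
    for r in range(n_rep):
        t = 0.0
        s = 0
        m = 0
        p = 0
        t_on = 0.0
        while t < t_end:
            r_sw = kon if s == 0 else koff
            r_tx = km if s == 1 else 0.0
            r_dm = delta * m
            r_tl = kp * m if with_protein else 0.0
            r_dp = dp * p if with_protein else 0.0
            total = r_sw + r_tx + r_dm + r_tl + r_dp
            if total <= 0.0:
                break
            dt = np.random.exponential(1.0 / total)
            if t + dt >= t_end:
                if s == 1:
                    t_on += t_end - t
                t = t_end
                break
            if s == 1:
                t_on += dt
            t += dt
            u = np.random.random() * total
            if u < r_sw:
                s = 1 - s
            elif u < r_sw + r_tx:
                m += 1
            elif u < r_sw + r_tx + r_dm:
                m -= 1
            elif u < r_sw + r_tx + r_dm + r_tl:
                p += 1
            else:
                p -= 1
        state[r] = s
        mrna[r] = m
        prot[r] = p
        onf[r] = t_on / t_end
    return state, mrna, prot, onf


def gillespie_simulate(
    params: TelegraphParams,
    t_end: float,
    seed: int,
    n_replicates: int = 1,
    protein: ProteinKinetics | Mapping[str, float] | None = None,
) -> GillespieResult:
    """Exact SSA endpoints for the telegraph model (optional translation stage).

    Each replicate starts Off with zero molecules; callers should choose
    ``t_end >= 10 / min(delta, k_on + k_off)`` (and ``>= 10/delta_p`` with a
    protein stage) so endpoints approximate stationarity.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if protein is not None and not isinstance(protein, ProteinKinetics):
        protein = ProteinKinetics(**dict(protein))
    kp = protein.k_p if protein else 0.0
    dp = protein.delta_p if protein else 0.0
    state, mrna, prot, onf = _ssa_core(
        float(params.k_on),
        float(params.k_off),
        float(params.k_m),
        float(params.delta),
        float(kp),
        float(dp),
        protein is not None,
        float(t_end),
        int(n_replicates),
        int(seed) % (2**32),
    )
    return GillespieResult(
        promoter_state=state,
        mrna=mrna,
        protein=prot if protein is not None else None,
        on_fraction=onf,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_counts_tsv(distributions: Iterable[CountDistribution], path) -> None:
    """Write clones as TSV with columns clone_id, cell_id, count."""
    frames = [
        pd.DataFrame(
            {
                "clone_id": d.clone_id,
                "cell_id": np.arange(len(d)),
                "count": d.counts,
            }
        )
        for d in distributions
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> list[CountDistribution]:
    df = pd.read_csv(path, sep="\t")
    required = {"clone_id", "cell_id", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    out = []
    for clone_id, grp in df.groupby("clone_id", sort=True):
        out.append(
            CountDistribution(
                clone_id=str(clone_id),
                counts=grp.sort_values("cell_id")["count"].to_numpy(),
            )
        )
    return out


def write_params_yaml(params: TelegraphParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)


def read_params_yaml(path) -> TelegraphParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return TelegraphParams(**{k: float(d[k]) for k in ("k_on", "k_off", "k_m", "delta")})
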