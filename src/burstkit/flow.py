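"""Flow-cytometry event processing: density-mode scatter gating, clone
clustering, matched-mean noise-pair selection, and the Poisson MOI
calculation.

Gating keeps the events inside the smallest highest-density region of a 2D
kernel density estimate on (FSC, SSC) — a small gate centered on the scatter
density mode — which controls for cell-size/granularity extrinsic noise
without touching the fluorescence channel.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cluster import AgglomerativeClustering

from .moments import loglog_regression

FLOW_CHANNELS = ("FSC", "SSC", "GFP")
_KDE_GRID = 128


def validate_flow_table(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FLOW_CHANNELS if c not in events.columns]
    if missing:
        raise ValueError(f"flow table missing channels {missing}")
    if len(events) < 1:
        raise ValueError("flow table is empty")
    vals = events[list(FLOW_CHANNELS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("flow channels must be positive and finite")
    return events


@dataclass(frozen=True)
class GateSpec:
    retain_fraction: float = 0.5
    min_cells: int = 4000
    bandwidth: str = "silverman"

    def __post_init__(self) -> None:
        if not (0 < self.retain_fraction <= 1):
            raise ValueError("retain_fraction must be in (0, 1]")
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")


@dataclass
class GateReport:
    n_input: int
    n_retained: int
    effective_fraction: float
    enlarged: bool = False  # fraction grown to satisfy min_cells
    insufficient_events: bool = False  # fewer events than min_cells: kept all
    degenerate_kde: bool = False


def _scatter_density(events: pd.DataFrame, bandwidth: str) -> np.ndarray:
    """KDE density at each event, evaluated via a 128x128 grid on (FSC, SSC)."""
    xy = events[["FSC", "SSC"]].to_numpy(dtype=float).T
    kde = gaussian_kde(xy, bw_method=bandwidth)
    gx = np.linspace(xy[0].min(), xy[0].max(), _KDE_GRID)
    gy = np.linspace(xy[1].min(), xy[1].max(), _KDE_GRID)
    mx, my = np.meshgrid(gx, gy, indexing="ij")
    dens = kde(np.vstack([mx.ravel(), my.ravel()])).reshape(_KDE_GRID, _KDE_GRID)
    ix = np.clip(np.searchsorted(gx, xy[0]), 0, _KDE_GRID - 1)
    iy = np.clip(np.searchsorted(gy, xy[1]), 0, _KDE_GRID - 1)
    return dens[ix, iy]


def density_mode_gate(
    events: pd.DataFrame, gate: GateSpec = GateSpec()
) -> tuple[pd.DataFrame, GateReport]:
    """Retain the ceil(retain_fraction * n) events of highest scatter density.

    If that leaves fewer than ``min_cells`` events, the gate is enlarged until
    the floor is met (or every event kept), and the report flags it.  Retained
    sets are nested: a larger retain_fraction always yields a superset.
    """
    validate_flow_table(events)
    n = len(events)
    if n < gate.min_cells:
        return events.copy(), GateReport(
            n_input=n, n_retained=n, effective_fraction=1.0, insufficient_events=True
        )
    if n == 1:
        return events.copy(), GateReport(
            n_input=1, n_retained=1, effective_fraction=1.0, degenerate_kde=True
        )
    try:
        density = _scatter_density(events, gate.bandwidth)
    except np.linalg.LinAlgError:
        return events.copy(), GateReport(
            n_input=n, n_retained=n, effective_fraction=1.0, degenerate_kde=True
        )
    k = int(np.ceil(gate.retain_fraction * n))
    enlarged = False
    if k < gate.min_cells:
        k = min(gate.min_cells, n)
        enlarged = True
    # stable ordering: density descending, original position as tie-break
    order = np.lexsort((np.arange(n), -density))
    keep = np.sort(order[:k])
    return events.iloc[keep].copy(), GateReport(
        n_input=n, n_retained=k, effective_fraction=k / n, enlarged=enlarged
    )


def gate_robustness_scan(
    events: pd.DataFrame, fractions, min_cells: int = 1, channel: str = "GFP"
) -> pd.DataFrame:
    """Variance-vs-mean log-log slope of clone GFP moments at each gate size.

    ``events`` holds all clones (column clone_id); each fraction gates every
    clone, recomputes per-clone moments, and refits the scaling regression.
    """
    fractions = list(fractions)
    if not fractions:
        raise ValueError("fractions must be non-empty")
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if "clone_id" not in events.columns or events["clone_id"].nunique() < 2:
        raise ValueError("need >= 2 clones")
    rows = []
    groups = dict(tuple(events.groupby("clone_id")))
    for frac in fractions:
        spec = GateSpec(retain_fraction=frac, min_cells=min_cells)
        means, variances = [], []
        for _, grp in sorted(groups.items()):
            kept, _ = density_mode_gate(grp, spec)
            g = kept[channel].to_numpy(dtype=float)
            means.append(g.mean())
            variances.append(g.var(ddof=1))
        reg = loglog_regression(means, variances)
        rows.append(
            {
                "fraction": frac,
                "slope": reg.slope,
                "slope_se": reg.slope_se,
                "slope_ci_lo": reg.slope_ci[0],
                "slope_ci_hi": reg.slope_ci[1],
                "r2": reg.r2,
                "n_clones": reg.n,
            }
        )
    return pd.DataFrame(rows)


def cluster_clone_distributions(summaries: pd.DataFrame, k: int = 4) -> np.ndarray:
    """Ward hierarchical clustering on standardized (log10 mean, log10 CV).

    Labels are deterministic: clusters are renumbered 0..k-1 by ascending
    mean log10 expression.
    """
    n = len(summaries)
    if k < 1 or n < k:
        raise ValueError("need n >= k >= 1")
    feats = np.column_stack(
        [np.log10(summaries["mean"].to_numpy()), np.log10(summaries["cv"].to_numpy())]
    )
    if not np.all(np.isfinite(feats)):
        raise ValueError("mean and cv must be positive and finite")
    z = (feats - feats.mean(axis=0)) / np.where(feats.std(axis=0) > 0, feats.std(axis=0), 1.0)
    if k == 1:
        return np.zeros(n, dtype=int)
    raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(z)
    order = (
        pd.DataFrame({"label": raw, "lm": feats[:, 0]})
        .groupby("label")["lm"]
        .mean()
        .sort_values()
        .index
    )
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[r] for r in raw], dtype=int)


def select_noise_pairs(
    summaries: pd.DataFrame, labels: np.ndarray, mean_tol: float = 0.1
) -> pd.DataFrame:
    """Per cluster, the clone pair with |Δlog10 mean| <= mean_tol maximizing
    |Δlog10 CV| (exhaustive search; lexicographic clone_id tie-break)."""
    df = summaries.reset_index(drop=True).copy()
    df["label"] = np.asarray(labels)
    rows = []
    for label, grp in df.groupby("label"):
        best = None
        recs = grp.sort_values("clone_id").to_dict("records")
        for a, b in itertools.combinations(recs, 2):
            dmean = abs(np.log10(a["mean"]) - np.log10(b["mean"]))
            if dmean > mean_tol:
                continue
            dcv = abs(np.log10(a["cv"]) - np.log10(b["cv"]))
            key = (-dcv, a["clone_id"], b["clone_id"])
            if best is None or key < best[0]:
                best = (key, a, b, dmean, dcv)
        if best is None:
            warnings.warn(f"cluster {label}: no admissible pair within mean_tol={mean_tol}")
            continue
        _, a, b, dmean, dcv = best
        hi, lo = (a, b) if a["cv"] >= b["cv"] else (b, a)
        rows.append(
            {
                "cluster": label,
                "high_noise_clone": hi["clone_id"],
                "low_noise_clone": lo["clone_id"],
                "dlog10_mean": dmean,
                "dlog10_cv": dcv,
            }
        )
    return pd.DataFrame(rows, columns=[
        "cluster", "high_noise_clone", "low_noise_clone", "dlog10_mean", "dlog10_cv"
    ])


def infer_moi(fraction_positive: float) -> float:
    """Poisson multiplicity of infection from the infected-cell fraction:
    fraction = 1 - e^(-MOI), so MOI = -ln(1 - fraction)."""
    if not (0 <= fraction_positive < 1):
        raise ValueError("fraction_positive must be in [0, 1)")
    return float(-np.log1p(-fraction_positive))
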