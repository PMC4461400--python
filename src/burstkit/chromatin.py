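"""DNase-qPCR chromatin accessibility and its relation to burst kinetics.

Inaccessibility I of a promoter site is the fraction of its DNA resistant to
DNase I digestion, normalized to a reference locus: per amplicon the
resistant fraction is R = 2^(-ΔCt) with ΔCt = mean(treated Ct) -
mean(untreated Ct), and I = R_site / R_reference, clamped into [0, 1]
(triplicate qPCR noise can push the ratio slightly past the physical bound).
Higher I means more closed chromatin.  Uncertainty is propagated from the
triplicate Ct standard deviations by the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .moments import RegressionResult, loglog_regression

LN2 = np.log(2.0)


@dataclass
class QpcrMeasurement:
    clone_id: str
    site: str
    treated: np.ndarray
    untreated: np.ndarray

    def __post_init__(self) -> None:
        self.treated = np.asarray(self.treated, dtype=float)
        self.untreated = np.asarray(self.untreated, dtype=float)
        for name, arr in (("treated", self.treated), ("untreated", self.untreated)):
            if arr.size < 2:
                raise ValueError(f"{name} Ct series needs >= 2 replicates")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name} Ct values must be positive and finite")
            if arr.size < 3:
                warnings.warn(f"{self.clone_id}/{self.site}: fewer than 3 {name} replicates")

    @property
    def delta_ct(self) -> float:
        return float(self.treated.mean() - self.untreated.mean())

    @property
    def delta_ct_var(self) -> float:
        """Variance of ΔCt from replicate scatter (variance of the means)."""
        return float(
            self.treated.var(ddof=1) / self.treated.size
            + self.untreated.var(ddof=1) / self.untreated.size
        )


@dataclass
class InaccessibilityResult:
    clone_id: str
    site: str
    inaccessibility: float
    sd: float
    clamped: bool


def inaccessibility_from_ct(
    target: QpcrMeasurement, reference: QpcrMeasurement
) -> InaccessibilityResult:
    """I = 2^-(ΔCt_target - ΔCt_reference), clamped to [0, 1] with a flag."""
    if target.clone_id != reference.clone_id:
        raise ValueError("target and reference must come from the same clone")
    log2_i = -(target.delta_ct - reference.delta_ct)
    i_raw = 2.0 ** log2_i
    clamped = bool(i_raw > 1.0)
    i = min(i_raw, 1.0)
    # delta method on log2 I: Var(I) = (I ln2)^2 Var(log2 I)
    sd = float(i_raw * LN2 * np.sqrt(target.delta_ct_var + reference.delta_ct_var))
    return InaccessibilityResult(
        clone_id=target.clone_id, site=target.site, inaccessibility=float(i), sd=sd, clamped=clamped
    )


def profiles_from_qpcr(qpcr: pd.DataFrame, reference_site: str = "reference") -> pd.DataFrame:
    """Tidy qPCR table -> per clone/site inaccessibility profile.

    Expects columns clone_id, site, condition (treated/untreated), replicate, Ct.
    """
    required = {"clone_id", "site", "condition", "Ct"}
    if not required.issubset(qpcr.columns):
        raise ValueError(f"qPCR table must have columns {sorted(required)}")
    rows = []
    for clone_id, grp in qpcr.groupby("clone_id", sort=True):
        sites = {}
        for site, sgrp in grp.groupby("site"):
            treated = sgrp.loc[sgrp["condition"] == "treated", "Ct"].to_numpy()
            untreated = sgrp.loc[sgrp["condition"] == "untreated", "Ct"].to_numpy()
            if untreated.size == 0:
                raise ValueError(f"{clone_id}/{site}: missing untreated series")
            sites[site] = QpcrMeasurement(str(clone_id), site, treated, untreated)
        if reference_site not in sites:
            raise ValueError(f"{clone_id}: missing reference site {reference_site!r}")
        ref = sites.pop(reference_site)
        for site, meas in sorted(sites.items()):
            res = inaccessibility_from_ct(meas, ref)
            rows.append(
                {
                    "clone_id": res.clone_id,
                    "site": site,
                    "inaccessibility": res.inaccessibility,
                    "sd": res.sd,
                    "clamped": res.clamped,
                }
            )
    return pd.DataFrame(rows)


def noise_pair_ratio(
    profiles: pd.DataFrame, pairs: pd.DataFrame, site: str
) -> pd.DataFrame:
    """I_high_noise / I_low_noise per matched-mean pair at one site.

    The >1-in-all-cases pattern is an observation to be made on data, not an
    enforced property.  Per-pair failures (missing clone, zero denominator)
    are recorded and the batch continues.
    """
    sub = profiles[profiles["site"] == site].set_index("clone_id")
    rows = []
    for _, pair in pairs.iterrows():
        hi, lo = pair["high_noise_clone"], pair["low_noise_clone"]
        rec = {"high_noise_clone": hi, "low_noise_clone": lo, "site": site}
        try:
            if hi not in sub.index or lo not in sub.index:
                raise KeyError(f"pair ({hi}, {lo}) not resolvable in profiles")
            ih, il = sub.loc[hi], sub.loc[lo]
            if il["inaccessibility"] == 0:
                raise ZeroDivisionError(f"pair ({hi}, {lo}): zero denominator")
            ratio = ih["inaccessibility"] / il["inaccessibility"]
            rel_var = 0.0
            if ih["inaccessibility"] > 0:
                rel_var += (ih["sd"] / ih["inaccessibility"]) ** 2
            rel_var += (il["sd"] / il["inaccessibility"]) ** 2
            rec.update(ratio=float(ratio), sd=float(ratio * np.sqrt(rel_var)), error="")
        except (KeyError, ZeroDivisionError) as exc:
            rec.update(ratio=np.nan, sd=np.nan, error=str(exc))
        rows.append(rec)
    return pd.DataFrame(rows)


def kinetics_accessibility_regression(
    profiles: pd.DataFrame, fits: pd.DataFrame, site: str
) -> dict[str, RegressionResult]:
    """Log-log regressions linking site inaccessibility to fitted kinetics.

    Headline orientation regresses burst frequency on I
    (``burst_freq_on_inaccessibility``); the reverse orientation and the
    burst-size regression (expected uncorrelated) are reported alongside.
    """
    sub = profiles[profiles["site"] == site]
    if sub.empty:
        raise ValueError(f"site {site!r} absent from profiles")
    merged = sub.merge(fits, on="clone_id", how="inner")
    if len(merged) < 3:
        raise ValueError("need >= 3 clones with both inaccessibility and fits")
    i = merged["inaccessibility"].to_numpy()
    return {
        "burst_freq_on_inaccessibility": loglog_regression(i, merged["burst_freq"]),
        "inaccessibility_on_burst_freq": loglog_regression(merged["burst_freq"], i),
        "burst_size_on_inaccessibility": loglog_regression(i, merged["burst_size"]),
    }


@dataclass
class PcaResult:
    variables: list[str]
    loadings: np.ndarray  # (n_variables, n_components)
    explained_variance_ratio: np.ndarray
    burst_freq_projection: np.ndarray  # loading of log10 f across components


def chromatin_pca(profiles: pd.DataFrame, fits: pd.DataFrame) -> PcaResult:
    """PCA (correlation scale) of log10 site inaccessibilities and log10 f̂.

    Columns are standardized to zero mean/unit variance and decomposed by
    SVD.  Sign convention: within each component the largest-magnitude
    loading is made positive, so output is deterministic.
    """
    wide = profiles.pivot(index="clone_id", columns="site", values="inaccessibility")
    merged = wide.merge(
        fits.set_index("clone_id")[["burst_freq"]], left_index=True, right_index=True
    )
    if len(merged) < 3:
        raise ValueError("need >= 3 clones")
    if merged.shape[1] < 2:
        raise ValueError("need >= 2 variables")
    variables = [f"log10_I_{c}" for c in wide.columns] + ["log10_burst_freq"]
    X = np.log10(merged.to_numpy(dtype=float))
    sd = X.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant columns: {[variables[j] for j in constant]}")
    Z = (X - X.mean(axis=0)) / sd
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt.T  # columns are components
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
    evr = s**2 / np.sum(s**2)
    return PcaResult(
        variables=variables,
        loadings=loadings,
        explained_variance_ratio=evr,
        burst_freq_projection=loadings[-1, :],
    )
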