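"""Seeded synthetic clone cohorts with the statistical structure of a
lentiviral integration-site study.

Each clone is one genomic integration site of the same promoter.  Clone-level
burst size b and normalized On rate f are drawn *independently* (the
orthogonal-control structure: b sets the mean, f sets the noise); per-cell
mRNA counts come from the stationary telegraph law with a transcription rate
λ shared across clones (δ = 1 sets the time unit).  Around the counts the
generator emulates the study's other readouts:

* a buffered fluorescent-protein readout (long-lived reporter, δ_p ≪ δ) whose
  clone-level moments track the RNA moments, with lognormal autofluorescence
  and scatter channels independent of fluorescence;
* a DNase-qPCR chromatin panel in which log10 inaccessibility at each
  promoter site is coupled log-linearly to log10 f (strongest at Nuc-1), with
  triplicate Ct noise;
* a transcription-inhibition decay time course with exponential target decay
  against a stable reference transcript.

Default calibration: log10 b ~ Normal(0.9, 0.4), log10 f ~ Normal(-0.4,
0.283), both truncated at ±2σ, λ = 1000, 200 clones x 600 cells.  The 2:1
log-variance ratio of b to f puts the cohort's variance-vs-mean log-log slope
near (2σ_b² + σ_f²)/(σ_b² + σ_f²) ≈ 1.67 — the bursty regime between Poisson
scaling (1) and pure burst-size modulation (2) — and the CV-vs-f slope near
the burst-limit value -1/2.

RNG spawning rule: a single cohort seed deterministically derives independent
streams via ``SeedSequence((seed, tag, index))`` — tag 0: clone-level (b, f)
and chromatin-truth draws; tag 1, clone i: that clone's counts; tag 2, clone
i: that clone's flow events; tag 3: qPCR triplicate noise; tag 4: decay-course
noise.  Per-clone results are therefore independent of evaluation order, and
any single clone can be regenerated alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .telegraph import (
    CountDistribution,
    ProteinKinetics,
    TelegraphParams,
    analytic_moments,
    gillespie_simulate,
    sample_stationary,
    write_counts_tsv,
)

CHROMATIN_SITES = ("Nuc-1", "HSS", "Nuc-0")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Log10Dist:
    """Truncated normal on the log10 scale."""

    family: str = "normal"
    location: float = 0.0
    scale: float = 1.0
    truncation_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.family != "normal":
            raise ConfigError(f"unsupported distribution family {self.family!r}")
        if self.scale < 0 or self.truncation_sigma <= 0:
            raise ConfigError("scale must be >= 0 and truncation_sigma > 0")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Linear-scale draws (10**x); zero scale collapses to the location."""
        if self.scale == 0:
            return np.full(size, 10.0 ** self.location)
        t = self.truncation_sigma
        x = truncnorm.rvs(-t, t, loc=self.location, scale=self.scale, size=size, random_state=rng)
        vals = 10.0 ** x
        if np.any(vals <= 0):  # pragma: no cover - 10**x is always positive
            raise ConfigError("truncation produced non-positive values")
        return vals


@dataclass(frozen=True)
class ProteinConfig:
    k_p: float = 5.0
    delta_p: float = 0.02  # δ/50: long-lived reporter buffers mRNA noise
    fluorescence_scale: float = 1.0
    autofluor_log_mean: float = 4.6  # natural-log lognormal, ~100 RFU
    autofluor_log_sd: float = 0.3
    fsc_log_mean: float = 11.5
    fsc_log_sd: float = 0.15
    ssc_log_mean: float = 11.0
    ssc_log_sd: float = 0.20
    method: str = "ssa"  # "ssa" (exact) or "moment" (fast approximation)
    scatter_gfp_coupling: float = 0.0  # testing knob; 0 = independent scatter


@dataclass(frozen=True)
class SiteCoupling:
    """log10 I = a0 + a1 * log10 f + Normal(0, noise_sd), clamped to (0, 1]."""

    a0: float
    a1: float
    noise_sd: float


@dataclass(frozen=True)
class QpcrConfig:
    ct_sd: float = 0.1  # triplicate Ct noise
    n_replicates: int = 3
    reference_resistant_fraction: float = 0.9  # protected fraction at the reference locus
    untreated_ct_target: float = 24.0
    untreated_ct_reference: float = 22.0

    def __post_init__(self) -> None:
        if not (0 < self.reference_resistant_fraction <= 1):
            raise ConfigError("reference_resistant_fraction must be in (0, 1]")


def _default_chromatin() -> dict[str, SiteCoupling]:
    # Nuc-1 carries the strongest, cleanest coupling to burst frequency;
    # HSS and Nuc-0 are weaker and noisier predictors.
    return {
        "Nuc-1": SiteCoupling(a0=-0.85, a1=-0.63, noise_sd=0.15),
        "HSS": SiteCoupling(a0=-0.60, a1=-0.40, noise_sd=0.25),
        "Nuc-0": SiteCoupling(a0=-0.70, a1=-0.30, noise_sd=0.30),
    }


@dataclass(frozen=True)
class CohortConfig:
    n_clones: int = 200
    cells_per_clone: int = 600
    log10_burst_size_dist: Log10Dist = field(
        default_factory=lambda: Log10Dist(location=0.9, scale=0.4)
    )
    log10_burst_freq_dist: Log10Dist = field(
        default_factory=lambda: Log10Dist(location=-0.4, scale=0.283)
    )
    lam_fixed: float = 1000.0
    protein: ProteinConfig = field(default_factory=ProteinConfig)
    chromatin: dict[str, SiteCoupling] = field(default_factory=_default_chromatin)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1 or self.cells_per_clone < 1:
            raise ConfigError("n_clones and cells_per_clone must be >= 1")
        if self.lam_fixed <= 0:
            raise ConfigError("lam_fixed must be > 0")
        missing = [s for s in CHROMATIN_SITES if s not in self.chromatin]
        if missing:
            raise ConfigError(f"chromatin config missing sites {missing}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chromatin"] = {k: asdict(v) for k, v in self.chromatin.items()}
        return d


def _clone_seed(seed: int, tag: int, index: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(seed), int(tag), int(index)))


def clone_params(truth_row, lam: float) -> TelegraphParams:
    """TelegraphParams of one truth-table row (δ = 1)."""
    return TelegraphParams.from_bursts(
        burst_size=float(truth_row["burst_size"]),
        burst_freq=float(truth_row["burst_freq"]),
        lam=lam,
    )


@dataclass
class Cohort:
    config: CohortConfig
    truth: pd.DataFrame
    counts: list[CountDistribution]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw per-clone (b, f) independently, record ground truth, and sample
    per-cell counts from each clone's stationary law."""
    n = config.n_clones
    rng0 = np.random.default_rng(_clone_seed(config.seed, 0))
    b = config.log10_burst_size_dist.draw(rng0, n)
    f = config.log10_burst_freq_dist.draw(rng0, n)

    eps = {site: rng0.normal(0.0, sc.noise_sd, size=n) for site, sc in config.chromatin.items()}

    rows = []
    counts: list[CountDistribution] = []
    width = len(str(n - 1))
    for i in range(n):
        cid = f"clone_{i:0{width}d}"
        params = TelegraphParams.from_bursts(b[i], f[i], config.lam_fixed)
        mom = analytic_moments(params)
        row = {
            "clone_id": cid,
            "clone_index": i,
            "burst_size": b[i],
            "burst_freq": f[i],
            "k_on": params.k_on,
            "k_off": params.k_off,
            "alpha": params.alpha,
            "beta": params.beta,
            "true_mean": mom.mean,
            "true_variance": mom.variance,
            "true_cv": mom.cv,
            "true_fano": mom.fano,
            "protein_scale": config.protein.fluorescence_scale,
        }
        for site, sc in config.chromatin.items():
            log10_i = sc.a0 + sc.a1 * np.log10(f[i]) + eps[site][i]
            row[f"inaccessibility_{site}"] = min(10.0 ** log10_i, 1.0)
        rows.append(row)
        counts.append(
            sample_stationary(
                params,
                config.cells_per_clone,
                seed=_clone_seed(config.seed, 1, i),
                clone_id=cid,
            )
        )
    return Cohort(config=config, truth=pd.DataFrame(rows), counts=counts)


def generate_loguniform_cohort(
    n_clones: int = 25,
    cells_per_clone: int = 600,
    burst_size_range: tuple[float, float] = (2.0, 50.0),
    burst_freq_range: tuple[float, float] = (0.1, 2.0),
    lam: float = 1000.0,
    seed: int = 1,
) -> Cohort:
    """Small validation cohort with (b, f) log-uniform over fixed ranges.

    Used for parameter-recovery checks where the bursty regime (b >= 2) must
    hold for every clone, unlike the lognormal default whose tails can dip
    below it.  Same per-clone seed-stream layout as :func:`generate_cohort`.
    """
    cfg = CohortConfig(n_clones=n_clones, cells_per_clone=cells_per_clone,
                       lam_fixed=lam, seed=seed)
    rng0 = np.random.default_rng(_clone_seed(seed, 5))
    b = 10.0 ** rng0.uniform(*np.log10(burst_size_range), n_clones)
    f = 10.0 ** rng0.uniform(*np.log10(burst_freq_range), n_clones)
    rows, counts = [], []
    width = len(str(n_clones - 1))
    for i in range(n_clones):
        cid = f"clone_{i:0{width}d}"
        params = TelegraphParams.from_bursts(b[i], f[i], lam)
        mom = analytic_moments(params)
        rows.append(
            {
                "clone_id": cid,
                "clone_index": i,
                "burst_size": b[i],
                "burst_freq": f[i],
                "true_mean": mom.mean,
                "true_cv": mom.cv,
            }
        )
        counts.append(
            sample_stationary(params, cells_per_clone, seed=_clone_seed(seed, 6, i), clone_id=cid)
        )
    return Cohort(config=cfg, truth=pd.DataFrame(rows), counts=counts)


def regenerate_clone_counts(config: CohortConfig, truth_row) -> CountDistribution:
    """Re-draw one clone's counts from its recorded seed stream."""
    params = clone_params(truth_row, config.lam_fixed)
    return sample_stationary(
        params,
        config.cells_per_clone,
        seed=_clone_seed(config.seed, 1, int(truth_row["clone_index"])),
        clone_id=str(truth_row["clone_id"]),
    )


# ---------------------------------------------------------------------------
# Protein / flow readout
# ---------------------------------------------------------------------------


def generate_protein_readout(
    params: TelegraphParams,
    config: CohortConfig,
    n_events: int,
    seed: int | np.random.SeedSequence,
    clone_id: str = "clone",
    method: str | None = None,
) -> pd.DataFrame:
    """Flow-like event table (FSC, SSC, GFP) for one clone.

    ``method="ssa"`` runs the exact simulation with the translation stage;
    ``method="moment"`` is the documented fast approximation: protein per
    event ∝ the average of K = δ/δ_p independent stationary mRNA draws, which
    reproduces the temporal averaging of a reporter that integrates mRNA over
    ~K degradation lifetimes.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    pc = config.protein
    if pc is None:
        raise ConfigError("protein config required")
    method = method or pc.method
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    ssa_seed_ss, noise_ss = ss.spawn(2)
    rng = np.random.default_rng(noise_ss)

    if method == "ssa":
        t_end = 10.0 / min(pc.delta_p, params.delta)
        ssa_seed = int(ssa_seed_ss.generate_state(1)[0])  # uint32 word
        res = gillespie_simulate(
            params,
            t_end=t_end,
            seed=ssa_seed,
            n_replicates=n_events,
            protein=ProteinKinetics(k_p=pc.k_p, delta_p=pc.delta_p),
        )
        protein = res.protein.astype(float)
    elif method == "moment":
        k_windows = max(1, int(round(params.delta / pc.delta_p)))
        rng_m = np.random.default_rng(ssa_seed_ss)
        a, b, lam = params.alpha, params.beta, params.lam
        if lam == 0 or a == 0:
            m = np.zeros((n_events, k_windows))
        else:
            x = np.ones((n_events, k_windows)) if b == 0 else rng_m.beta(a, b, (n_events, k_windows))
            m = rng_m.poisson(lam * x).astype(float)
        protein = (pc.k_p / pc.delta_p) * m.mean(axis=1)
    else:
        raise ValueError(f"unknown protein method {method!r}")

    autofluor = rng.lognormal(pc.autofluor_log_mean, pc.autofluor_log_sd, n_events)
    gfp = pc.fluorescence_scale * protein + autofluor
    fsc = rng.lognormal(pc.fsc_log_mean, pc.fsc_log_sd, n_events)
    ssc = rng.lognormal(pc.ssc_log_mean, pc.ssc_log_sd, n_events)
    if pc.scatter_gfp_coupling != 0.0:
        fsc = fsc * (gfp / np.median(gfp)) ** pc.scatter_gfp_coupling
    return pd.DataFrame({"clone_id": clone_id, "FSC": fsc, "SSC": ssc, "GFP": gfp})


def generate_cohort_flow(
    cohort: Cohort, n_events: int, method: str | None = None
) -> pd.DataFrame:
    """Flow events for every clone in a cohort (per-clone seed streams)."""
    frames = []
    for _, row in cohort.truth.iterrows():
        params = clone_params(row, cohort.config.lam_fixed)
        frames.append(
            generate_protein_readout(
                params,
                cohort.config,
                n_events,
                seed=_clone_seed(cohort.config.seed, 2, int(row["clone_index"])),
                clone_id=str(row["clone_id"]),
                method=method,
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Chromatin qPCR panel
# ---------------------------------------------------------------------------


def generate_chromatin_panel(
    truth: pd.DataFrame, config: CohortConfig, seed: int | None = None
) -> pd.DataFrame:
    """DNase-qPCR Ct table (clone x site x treated/untreated x replicate).

    Ct values are constructed so the ΔCt resistant-fraction ratio inverts to
    each clone's true inaccessibility up to triplicate noise: the treated Ct
    rises by -log2(I_site * R_ref) over the untreated Ct at promoter sites
    and by -log2(R_ref) at the reference locus.
    """
    qp = config.qpcr
    rng = np.random.default_rng(_clone_seed(config.seed if seed is None else seed, 3))
    r_ref = qp.reference_resistant_fraction
    rows = []
    for _, row in truth.iterrows():
        sites = {site: row[f"inaccessibility_{site}"] for site in config.chromatin}
        sites["reference"] = 1.0  # I is defined relative to the reference locus
        for site, i_true in sites.items():
            if i_true <= 0:
                raise ConfigError(f"non-positive abundance for {row['clone_id']}/{site}")
            base = qp.untreated_ct_reference if site == "reference" else qp.untreated_ct_target
            dct = -np.log2(i_true * r_ref)
            for rep in range(qp.n_replicates):
                for condition, ct in (("untreated", base), ("treated", base + dct)):
                    rows.append(
                        {
                            "clone_id": row["clone_id"],
                            "site": site,
                            "condition": condition,
                            "replicate": rep,
                            "Ct": ct + rng.normal(0.0, qp.ct_sd),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decay time course
# ---------------------------------------------------------------------------


def generate_decay_timecourse(
    delta: float,
    timepoints,
    config: CohortConfig | None = None,
    ct_sd: float | None = None,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Transcription-inhibition qPCR course: treated target decays as
    e^(-δt) against a stable reference; untreated series flat up to noise."""
    t = np.asarray(sorted(timepoints), dtype=float)
    if t.size < 3 or 0.0 not in t:
        raise ValueError("need >= 3 timepoints including 0")
    if np.any(t < 0):
        raise ValueError("negative time")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    qp = (config.qpcr if config else QpcrConfig())
    sd = qp.ct_sd if ct_sd is None else ct_sd
    base_seed = config.seed if config else seed
    rng = np.random.default_rng(_clone_seed(base_seed, 4))
    rows = []
    for series in ("treated", "untreated"):
        for ti in t:
            # Ct = base - log2(abundance); treated target abundance e^{-δt}
            drop = delta * ti / np.log(2.0) if series == "treated" else 0.0
            for gene, base, shift in (
                ("target", qp.untreated_ct_target, drop),
                ("reference", qp.untreated_ct_reference, 0.0),
            ):
                for rep in range(n_replicates):
                    rows.append(
                        {
                            "series": series,
                            "gene": gene,
                            "time": ti,
                            "replicate": rep,
                            "Ct": base + shift + rng.normal(0.0, sd),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort directory output
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, out_dir, flow_events: int = 0) -> None:
    """Write counts TSV, truth TSV, qPCR CSV, optional flow CSV, and a
    manifest YAML echoing the full config and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts_tsv(cohort.counts, out / "counts.tsv")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    generate_chromatin_panel(cohort.truth, cohort.config).to_csv(
        out / "qpcr.csv", index=False
    )
    if flow_events > 0:
        generate_cohort_flow(cohort, flow_events).to_csv(out / "flow.csv", index=False)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)


def config_from_yaml(path) -> CohortConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("log10_burst_size_dist", "log10_burst_freq_dist"):
        if key in raw:
            raw[key] = Log10Dist(**raw[key])
    if "protein" in raw:
        raw["protein"] = ProteinConfig(**raw["protein"])
    if "qpcr" in raw:
        raw["qpcr"] = QpcrConfig(**raw["qpcr"])
    if "chromatin" in raw:
        raw["chromatin"] = {k: SiteCoupling(**v) for k, v in raw["chromatin"].items()}
    return CohortConfig(**raw)
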