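"""Synthetic communities, environments, calibrations and cultures.

Every pipeline stage is testable without downloads because this module
generates data with known ground truth:

* copy-number calibration points scattered around a known line;
* a station-by-lineage community whose true per-sample trophic indices
  follow a logistic response of TI_M to standardized log PAR (positive) and
  log nitrate+nitrite (negative), with environmental medians per
  latitudinal band taken from open-ocean surface climatology (high PAR and
  low N in the subtropics, the reverse toward high latitudes) and gene
  counts inflated by group-specific 18S copy numbers;
* grazer-prey batch cultures integrated from a continuous-time model
  (prey: net growth minus clearance-rate grazing; grazer: exponential or
  logistic growth) and sampled every 12-24 h with multiplicative
  measurement noise.

All draws derive from a single :func:`numpy.random.default_rng` seed and
are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .copy_correction import CF_PRESETS, CopyCalibrationPoint
from .tables import AbundanceTable, EnvTable, TaxonomyTable
from .trophic_annotation import TrophicAnnotationDB

# ---------------------------------------------------------------------------
# Copy-number calibration


def simulate_copy_dataset(
    slope: float,
    intercept: float,
    n: int,
    noise_sd: float,
    biovolume_range: tuple[float, float] = (65.0, 523.0),
    group: str = "other",
    seed: int | None = None,
) -> list[CopyCalibrationPoint]:
    """Calibration points from a known copies-vs-biovolume line.

    Biovolumes are uniform on the range (the small-protist window the
    correction targets); copies get additive Gaussian noise and are floored
    at one copy per cell.
    """
    if n < 2:
        raise ValueError("need n >= 2 calibration points")
    lo, hi = biovolume_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid biovolume range {biovolume_range}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    v = rng.uniform(lo, hi, n)
    c = intercept + slope * v + rng.normal(0.0, noise_sd, n) if noise_sd > 0 else intercept + slope * v
    c = np.maximum(c, 1.0)
    return [CopyCalibrationPoint(float(vi), float(ci), group) for vi, ci in zip(v, c)]


# ---------------------------------------------------------------------------
# Community simulator


@dataclass(frozen=True)
class BandConfig:
    """Median surface conditions of one latitudinal band."""

    name: str
    n_stations: int
    par_median: float  # mol photons m-2 d-1
    n_median: float  # NO3-+NO2-, umol L-1
    hbac_median: float  # cells mL-1
    temp_median: float  # degC
    salinity_median: float


#: Surface medians per latitudinal band: PAR decreases and nitrate+nitrite
#: increases toward high latitudes; heterotrophic bacteria stay near
#: 4-5 x 10^5 cells mL^-1 throughout. Station counts give the band weights.
DEFAULT_BANDS: tuple[BandConfig, ...] = (
    BandConfig("0-20", 36, 25.4, 0.89, 4.9e5, 26.6, 35.1),
    BandConfig("20-30", 17, 24.3, 0.03, 3.9e5, 24.7, 36.2),
    BandConfig("30-40", 37, 14.7, 0.13, 5.3e5, 19.5, 36.4),
    BandConfig("40-60", 14, 18.8, 17.3, 4.5e5, 7.1, 34.3),
)


@dataclass
class CommunitySimConfig:
    """Ground-truth parameters of the community generator.

    ``beta_par`` and ``beta_n`` act on the logit of the true mixotroph index
    per standard deviation of log10 PAR and log10 N: positive light and
    negative nutrient effects by default. ``ti_unknown`` reserves a fixed
    share of the community for trophically unannotatable lineages, so the
    three true indices sum to 1 - ti_unknown. Gene counts are cell
    abundances times the group correction factor, optionally jittered
    multiplicatively and multinomially resampled to ``sequencing_depth``
    reads (set ``None`` for a noise-free table).
    """

    n_stations: int = 104
    bands: Sequence[BandConfig] = DEFAULT_BANDS
    beta_par: float = 0.5
    beta_n: float = -1.0
    intercept_logit: float = -0.85  # baseline TI_M near 0.30
    logit_noise_sd: float = 0.3
    ti_unknown: float = 0.03
    autotroph_share: float = 0.31  # of the non-mixotroph annotated remainder
    n_lineages: Mapping[str, int] = field(
        default_factory=lambda: {"M": 15, "A": 20, "H": 25, "unknown": 3}
    )
    cf_map: Mapping[str, float] = field(default_factory=lambda: dict(CF_PRESETS["default"]))
    total_cells: float = 1e6
    cf_noise_sd: float = 0.0  # multiplicative log-sd on gene conversion
    sequencing_depth: int | None = 100_000
    cml_stations: int = 0  # first k stations also get a CML sample
    layer_effect: float = -0.6  # logit TI_M shift of CML relative to SUR
    par_sigma: float = 0.25  # log-normal spreads within band
    n_sigma: float = 0.8
    hbac_sigma: float = 0.3

    def __post_init__(self) -> None:
        if not (0 <= self.ti_unknown < 1):
            raise ValueError("ti_unknown must be in [0, 1)")
        if not (0 < self.autotroph_share < 1):
            raise ValueError("autotroph_share must be in (0, 1)")
        if min(self.par_sigma, self.n_sigma, self.hbac_sigma) <= 0:
            raise ValueError("spreads must be positive")
        if self.sequencing_depth is not None and self.sequencing_depth < 1:
            raise ValueError("sequencing depth must be >= 1")
        if self.cml_stations > self.n_stations:
            raise ValueError("cml_stations cannot exceed n_stations")


_MODE_TEMPLATES = {
    "M": (
        ("Eukaryota", "Hacrobia", "Haptophyta", "Prymnesiophyceae",
         "Prymnesiales", "Chrysochromulinaceae"),
        ("Eukaryota", "Alveolata", "Dinoflagellata", "Dinophyceae",
         "Gymnodiniales", "Kareniaceae"),
        ("Eukaryota", "Stramenopiles", "Ochrophyta", "Chrysophyceae",
         "Chromulinales", "Chromulinaceae"),
        ("Eukaryota", "Stramenopiles", "Ochrophyta", "Dictyochophyceae",
         "Florenciellales", "Florenciellaceae"),
    ),
    "A": (
        ("Eukaryota", "Archaeplastida", "Chlorophyta", "Mamiellophyceae",
         "Mamiellales", "Mamiellaceae"),
        ("Eukaryota", "Stramenopiles", "Ochrophyta", "Bacillariophyta",
         "Bacillariophyta_X", "Polar-centric-Mediophyceae"),
        ("Eukaryota", "Hacrobia", "Haptophyta", "Prymnesiophyceae",
         "Phaeocystales", "Phaeocystaceae"),
    ),
    "H": (
        ("Eukaryota", "Stramenopiles", "Opalozoa", "MAST-4", "MAST-4A", "MAST-4A_X"),
        ("Eukaryota", "Hacrobia", "Telonemia", "Telonemia_X", "Telonemia-Group-2",
         "Telonemia-Group-2_X"),
        ("Eukaryota", "Excavata", "Discoba", "Diplonemea", "Diplonemida", "Diplonemidae"),
    ),
    "unknown": (
        ("Eukaryota", "Eukaryota_XX", "Eukaryota_XXX", "Eukaryota_XXXX",
         "Eukaryota_XXXXX", "Eukaryota_XXXXXX"),
    ),
}


def build_lineage_catalog(
    n_lineages: Mapping[str, int],
) -> tuple[TaxonomyTable, TrophicAnnotationDB, dict[str, str]]:
    """Deterministic lineage ids, ranked paths, annotation DB and true modes.

    Annotated lineages alternate between species-level and genus-level DB
    entries to exercise the rank fallback; ``unknown`` lineages get names
    absent from the DB.
    """
    paths: dict[str, str] = {}
    truth: dict[str, str] = {}
    db = TrophicAnnotationDB()
    for mode, count in n_lineages.items():
        templates = _MODE_TEMPLATES[mode]
        for i in range(count):
            lid = f"{mode}_{i:03d}"
            stem = templates[i % len(templates)]
            genus = f"{mode}_genus_{i:03d}"
            species = f"{mode}_species_{i:03d}"
            paths[lid] = ";".join((*stem, genus, species))
            truth[lid] = mode
            if mode == "unknown":
                continue
            if i % 2 == 0:
                db.add(species, "species", mode, source="synthetic")
            else:
                db.add(genus, "genus", mode, source="synthetic")
    taxonomy = TaxonomyTable.from_paths(paths)
    return taxonomy, db, truth


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _lognormal_around(rng, median: float, sigma: float, size: int) -> np.ndarray:
    return median * np.exp(rng.normal(0.0, sigma, size))


@dataclass
class SimulatedCommunity:
    """A synthetic survey with its generating truth."""

    abundance: AbundanceTable  # gene mode
    cell_abundance: AbundanceTable
    taxonomy: TaxonomyTable
    annotation_db: TrophicAnnotationDB
    env: EnvTable
    true_ti: pd.DataFrame  # TI_M, TI_A, TI_H per sample (all-lineage denominator)
    true_modes: dict[str, str]
    true_bands: pd.Series  # latitudinal band name per sample
    config: CommunitySimConfig


def simulate_community(config: CommunitySimConfig | None = None, seed: int | None = None) -> SimulatedCommunity:
    """Draw a full synthetic survey: env, taxonomy, gene and cell tables."""
    config = config or CommunitySimConfig()
    rng = np.random.default_rng(seed)

    # stations and bands (band proportions follow the configured weights)
    weights = np.array([b.n_stations for b in config.bands], dtype=float)
    weights /= weights.sum()
    band_idx = rng.choice(len(config.bands), size=config.n_stations, p=weights)
    stations = [f"ST{i + 1:03d}" for i in range(config.n_stations)]

    records = []
    for s, bi in zip(stations, band_idx):
        band = config.bands[bi]
        records.append((s, "SUR", band))
    for s, bi in zip(stations[: config.cml_stations], band_idx[: config.cml_stations]):
        band = config.bands[bi]
        records.append((s, "CML", band))

    n_samples = len(records)
    sample_ids = [f"{s}_{layer}" for s, layer, _ in records]
    layers = np.array([layer for _, layer, _ in records])

    par = np.empty(n_samples)
    nox = np.empty(n_samples)
    hbac = np.empty(n_samples)
    temp = np.empty(n_samples)
    sal = np.empty(n_samples)
    for i, (_, layer, band) in enumerate(records):
        par[i] = band.par_median * math.exp(rng.normal(0.0, config.par_sigma))
        nox[i] = band.n_median * math.exp(rng.normal(0.0, config.n_sigma))
        hbac[i] = band.hbac_median * math.exp(rng.normal(0.0, config.hbac_sigma))
        temp[i] = band.temp_median + rng.normal(0.0, 2.0)
        sal[i] = band.salinity_median + rng.normal(0.0, 0.5)
        if layer == "CML":
            par[i] *= 0.15 * math.exp(rng.normal(0.0, 0.3))
            nox[i] *= 2.5 * math.exp(rng.normal(0.0, 0.3))
            hbac[i] *= 0.8 * math.exp(rng.normal(0.0, 0.2))

    # true trophic indices via a logistic link on standardized log gradients
    log_par = np.log10(par)
    log_n = np.log10(nox)
    z_par = (log_par - log_par.mean()) / log_par.std(ddof=1)
    z_n = (log_n - log_n.mean()) / log_n.std(ddof=1)
    eta = (
        config.intercept_logit
        + config.beta_par * z_par
        + config.beta_n * z_n
        + config.layer_effect * (layers == "CML")
    )
    if config.logit_noise_sd > 0:
        eta = eta + rng.normal(0.0, config.logit_noise_sd, n_samples)
    ti_m = (1.0 - config.ti_unknown) * _sigmoid(eta)
    remainder = 1.0 - config.ti_unknown - ti_m
    ti_a = config.autotroph_share * remainder
    ti_h = remainder - ti_a
    shares = {"M": ti_m, "A": ti_a, "H": ti_h,
              "unknown": np.full(n_samples, config.ti_unknown)}

    taxonomy, db, true_modes = build_lineage_catalog(config.n_lineages)
    lineage_ids = taxonomy.lineage_ids

    cells = np.zeros((n_samples, len(lineage_ids)))
    col_of = {l: j for j, l in enumerate(lineage_ids)}
    for mode, count in config.n_lineages.items():
        cols = [col_of[l] for l in lineage_ids if true_modes[l] == mode]
        if not cols:
            continue
        w = np.exp(rng.normal(0.0, 1.0, (n_samples, len(cols))))
        w /= w.sum(axis=1, keepdims=True)
        cells[:, cols] = w * (shares[mode] * config.total_cells)[:, None]

    cell_df = pd.DataFrame(cells, index=pd.Index(sample_ids, name="sample_id"),
                           columns=lineage_ids)
    cell_table = AbundanceTable(cell_df, mode="cell")

    cf_vec = np.array([config.cf_map[taxonomy.cf_group(l)] for l in lineage_ids])
    gene = cells * cf_vec[None, :]
    if config.cf_noise_sd > 0:
        gene = gene * np.exp(rng.normal(0.0, config.cf_noise_sd, gene.shape))
    if config.sequencing_depth is not None:
        counts = np.empty_like(gene)
        for i in range(n_samples):
            p = gene[i] / gene[i].sum()
            counts[i] = rng.multinomial(config.sequencing_depth, p)
        gene = counts
    gene_table = AbundanceTable(
        pd.DataFrame(gene, index=cell_df.index, columns=lineage_ids), mode="gene"
    )

    env = _build_env_table(rng, sample_ids, [s for s, _, _ in records], layers,
                           par, nox, hbac, temp, sal)

    true_ti = pd.DataFrame(
        {"TI_M": ti_m, "TI_A": ti_a, "TI_H": ti_h},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SimulatedCommunity(
        abundance=gene_table,
        cell_abundance=cell_table,
        taxonomy=taxonomy,
        annotation_db=db,
        env=env,
        true_ti=true_ti,
        true_modes=true_modes,
        true_bands=pd.Series(
            [band.name for _, _, band in records],
            index=pd.Index(sample_ids, name="sample_id"),
            name="band",
        ),
        config=config,
    )


def _build_env_table(rng, sample_ids, station_ids, layers, par, nox, hbac, temp, sal) -> EnvTable:
    """Fill the full variable registry with band-structured and nuisance
    variables; correlations mimic broad oceanographic covariation (warm =
    oligotrophic and bright, cold = nutrient-rich)."""
    n = len(sample_ids)
    ln = lambda sigma: np.exp(rng.normal(0.0, sigma, n))  # noqa: E731
    chl = 0.08 + 0.12 * nox ** 0.5 * ln(0.4)
    kd = 0.035 + 0.02 * chl * ln(0.3)
    data = {
        "temperature": temp,
        "salinity": sal,
        "density": 1027.0 - 0.2 * (temp - 10.0) + 0.5 * (sal - 35.0) + rng.normal(0, 0.3, n),
        "kd_par": kd,
        "cml_depth": 90.0 / (1.0 + nox) ** 0.3 * ln(0.3),
        "mld": 25.0 * (1.0 + 0.1 * np.maximum(20.0 - temp, 0.0)) * ln(0.4),
        "nitracline_depth": 80.0 / (1.0 + nox) ** 0.4 * ln(0.3),
        "euphotic_depth": 4.6 / kd * ln(0.1),
        "par": par,
        "sunshine_duration": np.clip(6.0 + 0.2 * par + rng.normal(0, 1.0, n), 0.5, 16.0),
        "chl_a": chl,
        "oxygen": 320.0 - 3.0 * temp + rng.normal(0, 8.0, n),
        "no3_no2": nox,
        "no2": 0.05 * nox * ln(0.5) + 0.002,
        "po4": nox / 16.0 * ln(0.3) + 0.01,
        "sio4": 1.5 * nox ** 0.8 * ln(0.5) + 0.05,
        "ph": 8.05 + rng.normal(0, 0.03, n),
        "total_alkalinity": 2300.0 + 10.0 * (sal - 35.0) + rng.normal(0, 10.0, n),
        "total_carbon": 2050.0 + 2.0 * nox + rng.normal(0, 15.0, n),
        "fluorescence": chl * ln(0.2),
        "poc": 3.0 + 2.0 * chl * ln(0.3),
        "pic": 0.3 * ln(0.6),
        "cdom": 1.0 * ln(0.5),
        "co2": 400.0 + rng.normal(0, 15.0, n),
        "npp": 300.0 + 400.0 * chl * ln(0.3),
        "iron": 0.4 * ln(0.7),
        "prochlorococcus": 1.5e5 * np.exp(0.08 * (temp - 20.0)) * ln(0.4),
        "synechococcus": 2.0e4 * ln(0.6),
        "het_bacteria": hbac,
    }
    frame = pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"))
    frame.insert(0, "layer", layers)
    frame.insert(0, "station_id", station_ids)
    return EnvTable(frame)


# ---------------------------------------------------------------------------
# Culture simulator


@dataclass
class CultureSimConfig:
    """Ground truth for a grazer-prey batch culture.

    Continuous-time model on a 0.1 h grid: prey follows
    dP/dt = r_P P - C min(P, P_sat) G (clearance-rate grazing, optionally
    saturating above ``prey_sat``) and the grazer grows exponentially at
    ``mu_grazer`` (logistically toward ``grazer_K`` when set, producing a
    stationary phase). Cultures start near 2e6 prey cells mL^-1, the
    saturating-prey regime batch grazing assays target.
    """

    clearance: float = 2e-6  # mL grazer^-1 h^-1
    mu_grazer: float = 0.04  # h^-1
    prey0: float = 2e6  # cells mL^-1
    grazer0: float = 5e3  # cells mL^-1 inoculum
    prey_net_rate: float = 0.0  # h^-1, prey net change without grazers
    interval_h: float = 12.0
    horizon_h: float = 72.0
    noise_cv: float = 0.0
    replicates: int = 1
    grazer_biovolume: float = 100.0  # um^3
    grazer_K: float | None = None  # carrying capacity, cells mL^-1
    prey_sat: float | None = None  # saturation threshold, cells mL^-1
    integration_dt: float = 0.1  # h

    def __post_init__(self) -> None:
        if self.prey0 <= 0 or self.grazer0 <= 0:
            raise ValueError("initial concentrations must be positive")
        if not (12.0 <= self.interval_h <= 24.0):
            raise ValueError("sampling interval must lie in [12, 24] h")
        if self.horizon_h < 2 * self.interval_h:
            raise ValueError("horizon must cover at least two sampling intervals")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for name in ("clearance", "mu_grazer", "prey_net_rate"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class SimulatedCulture:
    """Sampled culture replicates plus the dense-grid truth."""

    replicates: list
    truth: dict


def _integrate_culture(config: CultureSimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-step RK4 of the prey/grazer/control system on the dense grid."""
    dt = config.integration_dt
    n_steps = int(round(config.horizon_h / dt))
    t = np.linspace(0.0, n_steps * dt, n_steps + 1)
    P = np.empty(n_steps + 1)
    G = np.empty(n_steps + 1)
    Pc = np.empty(n_steps + 1)
    P[0], G[0], Pc[0] = config.prey0, config.grazer0, config.prey0

    def deriv(p, g, pc):
        graze_p = min(p, config.prey_sat) if config.prey_sat else p
        dp = config.prey_net_rate * p - config.clearance * graze_p * g
        if config.grazer_K:
            dg = config.mu_grazer * g * (1.0 - g / config.grazer_K)
        else:
            dg = config.mu_grazer * g
        dpc = config.prey_net_rate * pc
        return dp, dg, dpc

    for i in range(n_steps):
        y = np.array([P[i], G[i], Pc[i]])
        k1 = np.array(deriv(*y))
        k2 = np.array(deriv(*(y + 0.5 * dt * k1)))
        k3 = np.array(deriv(*(y + 0.5 * dt * k2)))
        k4 = np.array(deriv(*(y + dt * k3)))
        P[i + 1], G[i + 1], Pc[i + 1] = np.maximum(
            y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0
        )
    return t, P, G, Pc


def simulate_culture(config: CultureSimConfig | None = None, seed: int | None = None) -> SimulatedCulture:
    """Integrate the culture model, sample it, and apply measurement noise."""
    from .culture_kinetics import CultureTimeSeries

    config = config or CultureSimConfig()
    rng = np.random.default_rng(seed)
    t, P, G, Pc = _integrate_culture(config)

    sample_idx = np.arange(
        0, len(t), int(round(config.interval_h / config.integration_dt))
    )
    ts_t = t[sample_idx]
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2)) if config.noise_cv > 0 else 0.0

    reps = []
    for r in range(config.replicates):
        if sigma > 0:
            noise = lambda size: np.exp(rng.normal(-0.5 * sigma**2, sigma, size))  # noqa: E731
            prey = P[sample_idx] * noise(len(sample_idx))
            grazer = G[sample_idx] * noise(len(sample_idx))
            control = Pc[sample_idx] * noise(len(sample_idx))
        else:
            prey, grazer, control = P[sample_idx], G[sample_idx], Pc[sample_idx]
        reps.append(
            CultureTimeSeries(
                times=ts_t.copy(),
                grazer=grazer,
                prey=prey,
                control_prey=control,
                grazer_biovolume=config.grazer_biovolume,
                replicate_id=f"r{r + 1}",
            )
        )

    graze_p = np.minimum(P, config.prey_sat) if config.prey_sat else P
    ingestion_truth = config.clearance * graze_p  # prey grazer^-1 h^-1 over time
    removed = np.trapezoid(config.clearance * graze_p * G, t)
    truth = {
        "clearance": config.clearance,
        "mu_grazer": config.mu_grazer,
        "prey_net_rate": config.prey_net_rate,
        "t_dense": t,
        "prey_dense": P,
        "grazer_dense": G,
        "control_dense": Pc,
        "ingestion_dense": ingestion_truth,
        "cumulative_removed": float(removed),
    }
    return SimulatedCulture(replicates=reps, truth=truth)
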