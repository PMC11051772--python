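"""Growth, ingestion and clearance rates from grazer-prey batch cultures.

A batch culture pairs a mixotrophic grazer with bacterial prey; both are
counted every 12-24 h. Per sampling interval [t, t+1]:

* ingestion I = (P_t - P_{t+1}) / (dt * mean(G_t, G_{t+1}))
  (prey grazer^-1 h^-1),
* clearance C = I / mean(P_t, P_{t+1}) (mL grazer^-1 h^-1),
* biovolume-specific clearance = C * 1e12 / V (body volumes grazer^-1 h^-1,
  with V the grazer biovolume in um^3; 1 mL = 1e12 um^3).

Reported means run over the intervals before the grazer reaches stationary
phase. The maximal growth rate is the steepest OLS slope of ln(grazer)
versus time over contiguous windows within the exponential phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

ML_PER_UM3 = 1e-12  # 1 mL = 1e12 um^3


@dataclass
class CultureTimeSeries:
    """Timed grazer and prey concentrations for one culture replicate."""

    times: np.ndarray  # hours, strictly increasing
    grazer: np.ndarray  # cells mL^-1
    prey: np.ndarray  # cells mL^-1
    control_prey: np.ndarray | None = None  # grazer-free control
    grazer_biovolume: float = 100.0  # um^3
    replicate_id: str = "r1"
    treatment: dict = field(default_factory=dict)  # e.g. light/nutrient levels

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.grazer = np.asarray(self.grazer, dtype=float)
        self.prey = np.asarray(self.prey, dtype=float)
        if self.control_prey is not None:
            self.control_prey = np.asarray(self.control_prey, dtype=float)
            if self.control_prey.shape != self.times.shape:
                raise ValueError("control_prey must align with times")
        if not (self.times.shape == self.grazer.shape == self.prey.shape):
            raise ValueError("times, grazer and prey must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if (self.grazer < 0).any() or (self.prey < 0).any():
            raise ValueError("concentrations must be non-negative")
        if self.grazer_biovolume <= 0:
            raise ValueError("grazer biovolume must be positive")
        dt = np.diff(self.times)
        if ((dt < 12) | (dt > 24)).any():
            warnings.warn(
                "sampling interval(s) outside the conventional 12-24 h range",
                stacklevel=2,
            )

    @property
    def n_intervals(self) -> int:
        return len(self.times) - 1


@dataclass
class GrowthFit:
    """Maximal exponential growth rate and the window it came from."""

    mu_max: float  # h^-1
    mu_max_per_day: float
    t_start: float
    t_end: float
    window: int


def exponential_growth_rate(ts: CultureTimeSeries, window: int = 3) -> GrowthFit:
    """Steepest ln(grazer)-vs-time OLS slope over contiguous windows.

    Windows containing non-positive grazer counts are skipped. By
    construction the result is >= the slope of any single valid window.
    """
    if window < 3:
        raise ValueError("window must span >= 3 observations")
    n = len(ts.times)
    if n < window:
        raise ValueError(f"need >= {window} observations, got {n}")
    best = None
    for i in range(n - window + 1):
        g = ts.grazer[i : i + window]
        if (g <= 0).any():
            continue
        t = ts.times[i : i + window]
        slope = stats.linregress(t, np.log(g)).slope
        if best is None or slope > best[0]:
            best = (float(slope), float(t[0]), float(t[-1]))
    if best is None:
        raise ValueError("no window free of zero/negative grazer counts")
    mu, t0, t1 = best
    return GrowthFit(mu_max=mu, mu_max_per_day=mu * 24.0, t_start=t0, t_end=t1, window=window)


def detect_stationary(ts: CultureTimeSeries, mu_threshold: float = 0.005) -> int:
    """Index of the first interval from which growth stays below threshold.

    Per-interval local slopes of ln(grazer) are compared against
    ``mu_threshold`` (h^-1); the onset is the earliest interval index i such
    that every interval from i on is below threshold. If growth never drops
    below the threshold the onset equals the number of intervals, i.e. every
    interval counts as pre-stationary.
    """
    if len(ts.times) < 3:
        raise ValueError("need >= 3 observations")
    dt = np.diff(ts.times)
    with np.errstate(divide="ignore", invalid="ignore"):
        lng = np.where(ts.grazer > 0, np.log(np.where(ts.grazer > 0, ts.grazer, 1.0)), np.nan)
    slopes = np.diff(lng) / dt
    below = slopes < mu_threshold  # NaN compares False: zero counts never stationary
    onset = ts.n_intervals
    for i in range(ts.n_intervals - 1, -1, -1):
        if below[i]:
            onset = i
        else:
            break
    return onset


@dataclass
class RateEstimates:
    """Per-interval and averaged grazing rates for one culture."""

    mu_max: float  # h^-1
    mu_max_per_day: float
    ingestion: np.ndarray  # prey grazer^-1 h^-1, per interval
    clearance_ml: np.ndarray  # mL grazer^-1 h^-1, per interval
    clearance_nl: np.ndarray  # nL grazer^-1 h^-1
    bv_clearance: np.ndarray  # body volumes grazer^-1 h^-1
    interval_valid: np.ndarray  # bool per interval (grazers present)
    negative_intervals: np.ndarray  # bool: prey grew faster than it was grazed
    stationary_onset_index: int
    mean_ingestion: float
    mean_clearance_ml: float
    mean_bv_clearance: float
    mean_clearance_ml_nonneg: float  # negatives excluded
    control_corrected: bool = False


def grazing_rates(
    ts: CultureTimeSeries,
    control_correction: bool = False,
    clip_negative: bool = False,
    mu_threshold: float = 0.005,
    growth_window: int = 3,
) -> RateEstimates:
    """Per-interval ingestion/clearance and their pre-stationary means.

    With ``control_correction`` the prey loss in each interval is measured
    against the prey's own net exponential change in the grazer-free
    control over the matching interval (prey that would have remained
    without grazing, minus prey observed). Negative per-interval ingestion
    (prey growth outpacing grazing) is preserved and flagged unless
    ``clip_negative``; the mean clearance is reported both with and without
    negative intervals.
    """
    n_int = ts.n_intervals
    if n_int < 1:
        raise ValueError("need >= 2 time points")
    if control_correction and ts.control_prey is None:
        raise ValueError("control_correction requested but no control series present")

    dt = np.diff(ts.times)
    ingestion = np.full(n_int, np.nan)
    clearance = np.full(n_int, np.nan)
    valid = np.zeros(n_int, dtype=bool)
    for i in range(n_int):
        g_mean = 0.5 * (ts.grazer[i] + ts.grazer[i + 1])
        if g_mean <= 0:
            warnings.warn(f"interval {i}: no grazers; skipped", stacklevel=2)
            continue
        p0, p1 = ts.prey[i], ts.prey[i + 1]
        if control_correction:
            c0, c1 = ts.control_prey[i], ts.control_prey[i + 1]
            if c0 > 0 and c1 > 0:
                # prey expected at t+1 had it only followed the control's net rate
                p_expected = p0 * (c1 / c0)
            else:
                p_expected = p0
            removed = p_expected - p1
        else:
            removed = p0 - p1
        I = removed / (dt[i] * g_mean)
        if clip_negative:
            I = max(I, 0.0)
        p_mean = 0.5 * (p0 + p1)
        ingestion[i] = I
        clearance[i] = I / p_mean if p_mean > 0 else np.nan
        valid[i] = True

    negative = np.where(np.isfinite(ingestion), ingestion < 0, False)
    if negative.any() and not clip_negative:
        warnings.warn(
            f"{int(negative.sum())} interval(s) with negative ingestion "
            "(prey net growth exceeded grazing)",
            stacklevel=2,
        )

    mu = float("nan")
    mu_day = float("nan")
    if len(ts.times) >= growth_window:
        try:
            fit = exponential_growth_rate(ts, window=growth_window)
            mu, mu_day = fit.mu_max, fit.mu_max_per_day
        except ValueError:
            pass
    onset = detect_stationary(ts, mu_threshold) if len(ts.times) >= 3 else n_int

    pre = np.zeros(n_int, dtype=bool)
    pre[:onset] = True
    use = pre & valid
    use_nonneg = use & ~negative

    def _mean(a: np.ndarray, m: np.ndarray) -> float:
        return float(np.nanmean(a[m])) if m.any() else float("nan")

    mean_i = _mean(ingestion, use)
    mean_c = _mean(clearance, use)
    mean_c_nonneg = _mean(clearance, use_nonneg)
    bv = clearance * (1.0 / ML_PER_UM3) / ts.grazer_biovolume

    return RateEstimates(
        mu_max=mu,
        mu_max_per_day=mu_day,
        ingestion=ingestion,
        clearance_ml=clearance,
        clearance_nl=clearance * 1e6,
        bv_clearance=bv,
        interval_valid=valid,
        negative_intervals=negative,
        stationary_onset_index=onset,
        mean_ingestion=mean_i,
        mean_clearance_ml=mean_c,
        mean_bv_clearance=mean_c * (1.0 / ML_PER_UM3) / ts.grazer_biovolume
        if np.isfinite(mean_c)
        else float("nan"),
        mean_clearance_ml_nonneg=mean_c_nonneg,
        control_corrected=control_correction,
    )
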