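"""Community-environment statistics.

Relates trophic indices to environmental gradients:

* Hellinger transform of community matrices for linear ordination;
* PCA of the (preprocessed) environmental table with a deterministic sign
  convention;
* penalized-spline smoothers of TI over principal-component axes with
  pointwise confidence bands and a shape summary;
* single-variable and AIC-stepwise linear regressions of TI;
* redundancy analysis (RDA) of the Hellinger species matrix on the
  environmental variables, preceded by an Escoufier equivalent-vectors
  species selection and per-variable significance (permutation) and
  collinearity (VIF) screens;
* one-way and main-effects ANOVA for the culture-rate experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable, EnvTable

# ---------------------------------------------------------------------------
# Hellinger transform


def hellinger(table: AbundanceTable) -> AbundanceTable:
    """Square root of row-relative abundances; rows get unit L2 norm.

    Zero-sum rows are emitted as all-zero with a warning.
    """
    if table.mode not in ("gene", "cell"):
        raise ValueError(f"hellinger expects gene or cell mode, got {table.mode!r}")
    values = table.values
    rowsum = values.sum(axis=1, keepdims=True)
    zero = rowsum[:, 0] <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-sum sample row(s) left as zeros", stacklevel=2
        )
    safe = np.where(rowsum > 0, rowsum, 1.0)
    out = pd.DataFrame(
        np.sqrt(values / safe), index=table.data.index, columns=table.data.columns
    )
    return AbundanceTable(out, mode="hellinger")


# ---------------------------------------------------------------------------
# PCA of the environmental table


@dataclass
class PcaResult:
    """Loadings (variables x components), scores (samples x components) and
    the variance fraction per axis."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    r2_per_axis: np.ndarray
    means: pd.Series
    sds: pd.Series | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca_env(env: EnvTable, standardize: bool = True, n_components: int | None = None) -> PcaResult:
    """PCA of the preprocessed environmental matrix.

    Columns are centered and, by default, z-scored (environmental variables
    carry incommensurate units). Sign convention: within each component the
    largest-magnitude loading is positive, making loading tables
    deterministic.
    """
    frame = env.variable_frame()
    if frame.isna().any().any():
        raise ValueError("environmental table contains missing values; run preprocess_env first")
    if frame.shape[1] < 2 or frame.shape[0] < 3:
        raise ValueError("PCA needs >= 3 samples and >= 2 variables")
    means = frame.mean()
    X = frame - means
    sds = None
    if standardize:
        sds = frame.std(ddof=1)
        constant = sds.index[(sds == 0) | sds.isna()].tolist()
        if constant:
            raise ValueError(f"constant variable(s) under z-scoring: {constant}")
        X = X / sds
    Xv = X.to_numpy()
    U, s, Vt = np.linalg.svd(Xv, full_matrices=False)
    k = min(len(s), n_components or len(s))
    # deterministic sign: largest |loading| positive per component
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = s**2
    r2 = var / var.sum()
    cols = [f"PC{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(Vt[:k].T, index=frame.columns, columns=cols)
    scores = pd.DataFrame((U[:, :k] * s[:k]), index=frame.index, columns=cols)
    return PcaResult(loadings=loadings, scores=scores, r2_per_axis=r2[:k], means=means, sds=sds)


# ---------------------------------------------------------------------------
# Penalized-spline smoother of TI over a gradient


@dataclass
class TrendFit:
    """A smoothed TI-vs-gradient trend with a pointwise 95% band."""

    predictor: str
    response: str
    grid: np.ndarray
    fitted: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    edf: float
    alpha: float
    shape: str  # increasing | decreasing | unimodal | flat | complex
    peak: float | None = None  # grid abscissa of the maximum, if unimodal


def _classify_shape(grid: np.ndarray, fitted: np.ndarray) -> tuple[str, float | None]:
    span = float(fitted.max() - fitted.min())
    xspan = float(grid.max() - grid.min())
    if span <= 1e-10 or xspan <= 0:
        return "flat", None
    deriv = np.gradient(fitted, grid)
    tol = 0.05 * span / xspan
    sign = np.where(deriv > tol, 1, np.where(deriv < -tol, -1, 0))
    nz = sign[sign != 0]
    if nz.size == 0:
        return "flat", None
    changes = np.flatnonzero(np.diff(nz) != 0)
    if len(changes) == 0:
        return ("increasing", None) if nz[0] > 0 else ("decreasing", None)
    if len(changes) == 1 and nz[0] > 0 and nz[-1] < 0:
        return "unimodal", float(grid[np.argmax(fitted)])
    return "complex", None


def fit_ti_smoother(
    x: np.ndarray,
    y: np.ndarray,
    predictor: str = "PC1",
    response: str = "TI",
    basis_df: int = 10,
    grid_size: int = 200,
) -> TrendFit:
    """Penalized cubic-spline smoother with automatic smoothness selection.

    The penalty weight is chosen by generalized cross-validation; the band
    is the pointwise 95% confidence interval of the fitted mean. The shape
    summary (increasing / decreasing / unimodal / flat, with ``complex`` as
    the fallback) is read off the sign pattern of the fitted derivative on
    the grid, not off the raw data.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 10:
        raise ValueError(f"need >= 10 paired observations, got {x.size}")
    k = basis_df
    if x.size < basis_df + 2:
        k = max(4, x.size - 2)
        warnings.warn(
            f"basis dimension shrunk from {basis_df} to {k} for n={x.size}",
            stacklevel=2,
        )
    bs = BSplines(x[:, None], df=[k], degree=[3], include_intercept=False)
    intercept = np.ones((x.size, 1))
    design_obs = np.column_stack([intercept, bs.transform(x[:, None])])
    grid = np.linspace(x.min(), x.max(), grid_size)
    design = np.column_stack([np.ones(grid_size), bs.transform(grid[:, None])])

    # degenerate (noise-free) data sit exactly in the basis span; the GLM
    # machinery cannot estimate a scale there, so fall back to plain OLS with
    # a zero-width band
    beta, _, rank, _ = np.linalg.lstsq(design_obs, y, rcond=None)
    resid = y - design_obs @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if np.sum(resid**2) <= max(tss, 1.0) * 1e-12:
        fitted = design @ beta
        alpha = 0.0
        band_lower = fitted.copy()
        band_upper = fitted.copy()
        edf = float(rank)
    else:
        gam = GLMGam(y, exog=intercept, smoother=bs)
        gam.fit()  # initializes the scale used by penalty-weight selection
        try:
            alpha = float(gam.select_penweight(criterion="gcv")[0][0])
        except Exception:  # singular search path on degenerate data
            alpha = 1.0
        res = GLMGam(y, exog=intercept, smoother=bs, alpha=alpha).fit()
        fitted = design @ res.params
        cov = np.asarray(res.cov_params())
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", design, cov, design), 0.0))
        band_lower = fitted - 1.96 * se
        band_upper = fitted + 1.96 * se
        scale = float(res.scale) if res.scale > 0 else 1.0
        edf = float(np.trace(cov @ (design_obs.T @ design_obs)) / scale)

    shape, peak = _classify_shape(grid, fitted)
    return TrendFit(
        predictor=predictor,
        response=response,
        grid=grid,
        fitted=fitted,
        band_lower=band_lower,
        band_upper=band_upper,
        edf=edf,
        alpha=alpha,
        shape=shape,
        peak=peak,
    )


# ---------------------------------------------------------------------------
# Linear regressions


@dataclass
class RegressionResult:
    """OLS summary for one TI response."""

    response: str
    predictors: list[str]
    coefficients: pd.DataFrame  # coef, se, p per term (incl. const)
    r_squared: float
    n: int
    aic: float
    trace: list[tuple[str, str, float]] = field(default_factory=list)

    def slope(self, name: str | None = None) -> float:
        name = name or self.predictors[0]
        return float(self.coefficients.loc[name, "coef"])

    def p_value(self, name: str | None = None) -> float:
        name = name or self.predictors[0]
        return float(self.coefficients.loc[name, "p"])


def _log10_shifted(x: np.ndarray) -> np.ndarray:
    if (x <= 0).any():
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError("predictor has no positive values to log-transform")
        return np.log10(x + 0.5 * positive.min())
    return np.log10(x)


def regress_ti(
    ti: np.ndarray,
    predictor: np.ndarray,
    predictor_name: str = "x",
    response_name: str = "TI",
    log_transform: bool = False,
) -> RegressionResult:
    """Single-variable OLS of a trophic index on a gradient."""
    y = np.asarray(ti, dtype=float).ravel()
    x = np.asarray(predictor, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError("response and predictor must have equal length")
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    if y.size < 3:
        raise ValueError(f"need >= 3 paired observations, got {y.size}")
    if log_transform:
        x = _log10_shifted(x)
    if np.ptp(x) == 0:
        raise ValueError(f"zero-variance predictor {predictor_name!r}")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    coef = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "p": res.pvalues},
        index=["const", predictor_name],
    )
    return RegressionResult(
        response=response_name,
        predictors=[predictor_name],
        coefficients=coef,
        r_squared=float(res.rsquared),
        n=int(res.nobs),
        aic=float(res.aic),
    )


def regress_ti_battery(
    ti: pd.Series,
    env_frame: pd.DataFrame,
    log_transform: bool = False,
) -> pd.DataFrame:
    """One regression per environmental variable, with BH q-values.

    Screening dozens of variables inflates false positives, so
    Benjamini-Hochberg q-values accompany the raw p-values.
    """
    rows = []
    for var in env_frame.columns:
        r = regress_ti(
            ti.to_numpy(),
            env_frame[var].to_numpy(),
            predictor_name=var,
            response_name=str(ti.name or "TI"),
            log_transform=log_transform,
        )
        rows.append(
            {"variable": var, "slope": r.slope(var), "p": r.p_value(var), "r2": r.r_squared}
        )
    out = pd.DataFrame(rows).set_index("variable")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def stepwise_ti(
    ti: pd.Series | np.ndarray,
    env_frame: pd.DataFrame,
    criterion: str = "aic",
    max_steps: int = 100,
) -> RegressionResult:
    """Bidirectional stepwise OLS from the intercept-only model.

    At each step the add or drop giving the largest criterion decrease is
    taken; the full trace of (action, variable, criterion) moves is
    recorded. When there are more candidates than observations the search
    runs forward-only.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    y = np.asarray(ti, dtype=float).ravel()
    X = env_frame.astype(float)
    if len(y) != len(X):
        raise ValueError("response and predictor table must align")
    if X.isna().any().any() or not np.isfinite(y).all():
        raise ValueError("stepwise selection needs complete cases")
    forward_only = X.shape[1] >= len(y)
    if forward_only:
        warnings.warn("more candidates than observations: forward-only search", stacklevel=2)

    def crit(cols: list[str]) -> float:
        design = sm.add_constant(X[cols]) if cols else np.ones((len(y), 1))
        res = sm.OLS(y, design).fit()
        return float(getattr(res, criterion))

    selected: list[str] = []
    current = crit(selected)
    trace: list[tuple[str, str, float]] = [("start", "", current)]
    for _ in range(max_steps):
        moves: list[tuple[float, str, str]] = []
        for var in X.columns:
            if var not in selected and len(selected) + 2 <= len(y):
                moves.append((crit(selected + [var]), "add", var))
        if not forward_only:
            for var in selected:
                moves.append((crit([v for v in selected if v != var]), "drop", var))
        if not moves:
            break
        best, action, var = min(moves, key=lambda m: m[0])
        if best >= current - 1e-10:
            break
        current = best
        if action == "add":
            selected.append(var)
        else:
            selected.remove(var)
        trace.append((action, var, current))
        # an (effectively) exact fit makes further AIC comparisons degenerate
        if selected:
            fit = sm.OLS(y, sm.add_constant(X[selected])).fit()
            tss = float(np.sum((y - y.mean()) ** 2))
            if fit.ssr <= 1e-12 * max(tss, 1.0):
                break

    design = sm.add_constant(X[selected]) if selected else np.ones((len(y), 1))
    res = sm.OLS(y, design).fit()
    names = ["const"] + selected if selected else ["const"]
    coef = pd.DataFrame({"coef": res.params, "se": res.bse, "p": res.pvalues})
    coef.index = names
    return RegressionResult(
        response=str(getattr(ti, "name", None) or "TI"),
        predictors=selected,
        coefficients=coef,
        r_squared=float(res.rsquared),
        n=int(res.nobs),
        aic=float(res.aic),
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Redundancy analysis with Escoufier species selection and env screening


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """Escoufier's RV between two column-centered matrices on the same rows."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxy = Xc.T @ Yc
    Sxx = Xc.T @ Xc
    Syy = Yc.T @ Yc
    denom = np.sqrt(np.sum(Sxx * Sxx) * np.sum(Syy * Syy))
    if denom == 0:
        return 0.0
    return float(np.sum(Sxy * Sxy) / denom)


def escoufier_select(values: np.ndarray, names: list[str], threshold: float = 0.9) -> list[str]:
    """Greedy equivalent-vectors selection of columns.

    Columns are added one at a time, each time picking the column whose
    inclusion maximizes the RV coefficient between the selected submatrix
    and the full matrix, stopping once RV >= threshold.
    """
    n_cols = values.shape[1]
    selected: list[int] = []
    remaining = list(range(n_cols))
    rv = 0.0
    while remaining and rv < threshold:
        best_rv, best_j = -1.0, None
        for j in remaining:
            cand = values[:, selected + [j]]
            r = rv_coefficient(cand, values)
            if r > best_rv:
                best_rv, best_j = r, j
        selected.append(best_j)
        remaining.remove(best_j)
        rv = best_rv
    return [names[j] for j in selected]


def _constrained_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Fraction of total variance of centered Y explained by centered X."""
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    sst = float(np.sum(Yc * Yc))
    if sst == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fit = Xc @ beta
    return float(np.sum(fit * fit) / sst)


@dataclass
class RdaResult:
    """Biplot coordinates and screening diagnostics of a redundancy analysis."""

    species_scores: pd.DataFrame
    sample_scores: pd.DataFrame
    env_arrows: pd.DataFrame
    constrained_fraction: float
    axis_fractions: np.ndarray
    permutation_p: pd.Series
    vif: pd.Series
    selected_species: list[str]
    selected_env: list[str]
    constrained: bool = True


def rda_species(
    species: AbundanceTable,
    env: EnvTable,
    escoufier_threshold: float = 0.9,
    n_perm: int = 999,
    vif_max: float = 10.0,
    alpha: float = 0.05,
    seed: int | None = None,
    n_axes: int = 2,
) -> RdaResult:
    """RDA of the Hellinger species matrix on screened env variables.

    Pipeline: (i) Escoufier equivalent-vectors selection reduces the species
    matrix to a subset carrying RV >= threshold with the full matrix;
    (ii) each environmental variable must pass a marginal permutation test
    (seeded, ``n_perm`` shuffles of that variable) at ``alpha`` and a
    collinearity screen (VIF <= ``vif_max``, worst variable dropped
    iteratively); (iii) the species matrix is regressed on the surviving
    variables and the fitted matrix decomposed by SVD into biplot
    coordinates. If no variable survives, the unconstrained ordination (PCA
    of the species matrix) is returned with a warning.
    """
    if species.mode != "hellinger":
        raise ValueError("rda_species expects a Hellinger-transformed table")
    env_frame = env.variable_frame()
    if list(species.sample_ids) != list(env_frame.index):
        env_frame = env_frame.reindex(species.sample_ids)
        if env_frame.isna().any().any():
            raise ValueError("species and env tables must cover the same samples")
    Y_full = species.values
    rng = np.random.default_rng(seed)

    picked = set(
        escoufier_select(Y_full, list(species.lineage_ids), threshold=escoufier_threshold)
    )
    # report/decompose in the table's original lineage order
    selected_species = [l for l in species.lineage_ids if l in picked]
    Y = species.data[selected_species].to_numpy()
    Yc = Y - Y.mean(axis=0)

    # marginal permutation screen per environmental variable
    p_values = {}
    for var in env_frame.columns:
        x = env_frame[var].to_numpy()[:, None]
        obs = _constrained_r2(Y, x)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(x[:, 0])[:, None]
            if _constrained_r2(Y, perm) >= obs:
                hits += 1
        p_values[var] = (1 + hits) / (1 + n_perm)
    permutation_p = pd.Series(p_values, name="p")
    survivors = [v for v in env_frame.columns if permutation_p[v] <= alpha]

    # collinearity screen: iteratively drop the worst VIF
    vifs = pd.Series(np.nan, index=env_frame.columns, name="vif")
    while len(survivors) > 1:
        X = env_frame[survivors].to_numpy()
        Xc = X - X.mean(axis=0)
        current = {}
        for j, var in enumerate(survivors):
            others = np.delete(Xc, j, axis=1)
            r2 = _constrained_r2(Xc[:, [j]], others) if others.shape[1] else 0.0
            current[var] = 1.0 / max(1.0 - r2, 1e-12)
        worst = max(current, key=current.get)
        for v, val in current.items():
            vifs[v] = val
        if current[worst] <= vif_max:
            break
        survivors.remove(worst)
    if len(survivors) == 1:
        vifs[survivors[0]] = 1.0

    axes = [f"RDA{j + 1}" for j in range(n_axes)]
    if not survivors:
        warnings.warn(
            "no environmental variable passed both screens; "
            "returning unconstrained ordination",
            stacklevel=2,
        )
        U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
        k = min(n_axes, len(s))
        frac = (s**2) / np.sum(s**2) if np.sum(s**2) > 0 else np.zeros_like(s)
        return RdaResult(
            species_scores=pd.DataFrame(Vt[:k].T, index=selected_species, columns=axes[:k]),
            sample_scores=pd.DataFrame(
                U[:, :k] * s[:k], index=species.sample_ids, columns=axes[:k]
            ),
            env_arrows=pd.DataFrame(columns=axes[:k]),
            constrained_fraction=float("nan"),
            axis_fractions=frac[:k],
            permutation_p=permutation_p,
            vif=vifs,
            selected_species=selected_species,
            selected_env=[],
            constrained=False,
        )

    X = env_frame[survivors].to_numpy()
    Xc = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Yhat = Xc @ beta
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    rank = int(np.sum(s > 1e-12 * max(s[0], 1.0)))
    k = min(n_axes, max(rank, 1))
    sst = float(np.sum(Yc * Yc))
    constrained_fraction = float(np.sum(s**2) / sst) if sst > 0 else 0.0
    axis_fractions = (s[:k] ** 2) / sst if sst > 0 else np.zeros(k)
    sample_scores = U[:, :k] * s[:k]
    with np.errstate(invalid="ignore"):
        arrows = np.array(
            [
                [
                    (np.corrcoef(Xc[:, j], sample_scores[:, a])[0, 1]
                     if np.std(sample_scores[:, a]) > 0 else 0.0)
                    for a in range(k)
                ]
                for j in range(len(survivors))
            ]
        )
    arrows = np.nan_to_num(arrows)
    return RdaResult(
        species_scores=pd.DataFrame(Vt[:k].T, index=selected_species, columns=axes[:k]),
        sample_scores=pd.DataFrame(sample_scores, index=species.sample_ids, columns=axes[:k]),
        env_arrows=pd.DataFrame(arrows, index=survivors, columns=axes[:k]),
        constrained_fraction=constrained_fraction,
        axis_fractions=np.asarray(axis_fractions),
        permutation_p=permutation_p,
        vif=vifs,
        selected_species=selected_species,
        selected_env=survivors,
        constrained=True,
    )


# ---------------------------------------------------------------------------
# ANOVA for culture rates


@dataclass
class AnovaResult:
    """F-test of one (or several main-effect) factors on a rate."""

    factors: tuple[str, ...]
    F: float
    p: float
    dfn: int
    dfd: int
    n: int


def _one_way(values: np.ndarray, groups: np.ndarray) -> AnovaResult:
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need >= 2 levels per tested factor")
    n = len(values)
    grand = values.mean()
    ssb = sum(
        len(values[groups == g]) * (values[groups == g].mean() - grand) ** 2
        for g in levels
    )
    ssw = sum(
        float(np.sum((values[groups == g] - values[groups == g].mean()) ** 2))
        for g in levels
    )
    dfn = len(levels) - 1
    dfd = n - len(levels)
    if dfd < 1:
        raise ValueError("saturated one-way model: no residual degrees of freedom")
    if ssb <= 1e-300:
        F, p = 0.0, 1.0
    elif ssw <= 1e-300:
        F, p = float("inf"), 0.0
    else:
        F = (ssb / dfn) / (ssw / dfd)
        p = float(stats.f.sf(F, dfn, dfd))
    return AnovaResult(factors=(), F=float(F), p=float(p), dfn=dfn, dfd=dfd, n=n)


def anova_rates(
    values: np.ndarray,
    factors: pd.DataFrame,
    multifactor_sets: list[tuple[str, ...]] | None = None,
) -> dict[tuple[str, ...], AnovaResult]:
    """Single-factor and multi-factor (main effects) ANOVAs of a rate.

    Returns one :class:`AnovaResult` per factor set: each single factor as a
    one-way ANOVA, then each requested combination as the overall F-test of
    the additive (main effects) OLS model with categorical dummies. The
    numerator df equals the summed (levels - 1) of the included factors.
    """
    y = np.asarray(values, dtype=float).ravel()
    if len(y) != len(factors):
        raise ValueError("values and factors must align")
    results: dict[tuple[str, ...], AnovaResult] = {}
    for f in factors.columns:
        r = _one_way(y, factors[f].to_numpy())
        results[(f,)] = AnovaResult(
            factors=(f,), F=r.F, p=r.p, dfn=r.dfn, dfd=r.dfd, n=r.n
        )
    if multifactor_sets is None:
        cols = tuple(factors.columns)
        multifactor_sets = [cols] if len(cols) > 1 else []
    for combo in multifactor_sets:
        dummies = pd.get_dummies(
            factors[list(combo)].astype(str), drop_first=True, dtype=float
        )
        X = sm.add_constant(dummies)
        if len(y) - X.shape[1] < 1:
            raise ValueError(f"saturated model for factors {combo}")
        res = sm.OLS(y, X).fit()
        dfn = int(res.df_model)
        dfd = int(res.df_resid)
        if res.ess <= 1e-300:
            F, p = 0.0, 1.0
        else:
            F, p = float(res.fvalue), float(res.f_pvalue)
        results[tuple(combo)] = AnovaResult(
            factors=tuple(combo), F=F, p=p, dfn=dfn, dfd=dfd, n=len(y)
        )
    return results
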