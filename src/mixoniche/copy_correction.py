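"""18S copy-number correction: calibration fits and gene-to-cell conversion.

18S rRNA gene copy numbers per cell scale with cellular biovolume but are
strongly inflated in some taxa (dinoflagellates above all, diatoms to a
lesser degree). Raw amplicon counts therefore over-represent those groups.
The correction fits, per group, an ordinary least-squares line of
copies-per-cell on biovolume from empirical calibration points, evaluates it
at a reference biovolume (65 um^3, the small-flagellate end of the
calibration range) to obtain a correction factor (C.F.), and divides each
lineage's gene counts by its group's C.F. to approximate cell abundances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CF_GROUPS, AbundanceTable, TaxonomyTable

#: Reference biovolume (um^3) at which correction factors are evaluated.
DEFAULT_V_REF = 65.0

#: Named correction-factor presets (copies per cell at the reference
#: biovolume). ``default`` is this package's calibration; ``martin2022`` is
#: an independently published alternative useful for sensitivity analysis.
CF_PRESETS: Mapping[str, Mapping[str, float]] = {
    "default": {"dinoflagellate": 59.3, "diatom": 10.5, "other": 4.7},
    "martin2022": {"dinoflagellate": 27.1, "diatom": 4.4, "other": 0.9},
}


@dataclass(frozen=True)
class CopyCalibrationPoint:
    """One empirical (biovolume, copies-per-cell) observation for a group."""

    biovolume: float  # um^3
    copies: float  # 18S copies per cell
    group: str

    def __post_init__(self) -> None:
        if self.biovolume <= 0:
            raise ValueError(f"biovolume must be positive, got {self.biovolume}")
        if self.copies < 1:
            raise ValueError(f"copies per cell must be >= 1, got {self.copies}")
        if self.group not in CF_GROUPS:
            raise ValueError(f"group must be one of {CF_GROUPS}, got {self.group!r}")


class DegenerateFitError(ValueError):
    """Raised when a calibration set cannot support a line fit."""


@dataclass
class CorrectionModel:
    """Per-group linear model of copies-per-cell on biovolume.

    ``cf`` is the fitted line evaluated at ``v_ref``.
    """

    group: str
    slope: float  # copies per um^3
    intercept: float  # copies
    v_ref: float = DEFAULT_V_REF
    n_points: int = 2
    r_squared: float = float("nan")
    residual_sd: float = float("nan")
    slope_se: float = float("nan")
    intercept_se: float = float("nan")

    @property
    def cf(self) -> float:
        return self.intercept + self.slope * self.v_ref


def fit_copy_model(
    points: Iterable[CopyCalibrationPoint],
    group: str,
    v_ref: float = DEFAULT_V_REF,
) -> CorrectionModel:
    """OLS fit of copies on biovolume over the calibration points of a group."""
    pts = [p for p in points if p.group == group]
    if len(pts) < 2:
        raise DegenerateFitError(
            f"need >= 2 calibration points for group {group!r}, got {len(pts)}"
        )
    v = np.array([p.biovolume for p in pts], dtype=float)
    c = np.array([p.copies for p in pts], dtype=float)
    if np.unique(v).size < 2:
        raise DegenerateFitError(
            f"all calibration biovolumes identical for group {group!r}"
        )
    if np.allclose(c, c[0]):
        # constant response: slope exactly 0, intercept the common value
        slope, intercept, r2 = 0.0, float(c[0]), 0.0
        slope_se = intercept_se = 0.0
        resid = c - intercept
    else:
        res = stats.linregress(v, c)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
        slope_se = float(res.stderr)
        intercept_se = float(res.intercept_stderr)
        resid = c - (intercept + slope * v)
    dof = len(pts) - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    model = CorrectionModel(
        group=group,
        slope=slope,
        intercept=intercept,
        v_ref=float(v_ref),
        n_points=len(pts),
        r_squared=r2,
        residual_sd=residual_sd,
        slope_se=slope_se,
        intercept_se=intercept_se,
    )
    if model.cf <= 0:
        raise DegenerateFitError(
            f"fitted correction factor {model.cf:.3g} <= 0 at v_ref={v_ref}; "
            "consider a through-origin or log-log refit"
        )
    return model


def correction_factor(model: CorrectionModel, v_ref: float = DEFAULT_V_REF) -> float:
    """Evaluate the fitted line at ``v_ref`` (updating the stored reference)."""
    cf = model.intercept + model.slope * float(v_ref)
    if cf <= 0:
        raise ValueError(
            f"correction factor {cf:.3g} <= 0 at v_ref={v_ref} for group "
            f"{model.group!r}"
        )
    model.v_ref = float(v_ref)
    return float(cf)


def read_calibration_csv(path) -> list[CopyCalibrationPoint]:
    """Read a ``group,biovolume_um3,copies_per_cell`` CSV."""
    df = pd.read_csv(path)
    needed = {"group", "biovolume_um3", "copies_per_cell"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: calibration CSV needs columns {sorted(needed)}")
    return [
        CopyCalibrationPoint(float(r.biovolume_um3), float(r.copies_per_cell), str(r.group))
        for r in df.itertuples()
    ]


def gene_to_cell(
    table: AbundanceTable,
    taxonomy: TaxonomyTable,
    cf_map: Mapping[str, float] | None = None,
    lineage_overrides: Mapping[str, float] | None = None,
) -> AbundanceTable:
    """Divide gene counts by each lineage's group correction factor.

    ``cf_map`` maps group name to C.F. (defaults to ``CF_PRESETS['default']``);
    ``lineage_overrides`` optionally pins a per-lineage divisor that takes
    precedence over the group value. Within-group relative composition is
    unchanged by construction.
    """
    if table.mode != "gene":
        raise ValueError(f"expected a gene-mode table, got mode={table.mode!r}")
    cf_map = dict(CF_PRESETS["default"] if cf_map is None else cf_map)
    overrides = dict(lineage_overrides or {})
    for g, cf in cf_map.items():
        if cf <= 0:
            raise ValueError(f"non-positive correction factor {cf} for group {g!r}")
    known = set(taxonomy.lineage_ids)
    missing = [l for l in table.lineage_ids if l not in known and l not in overrides]
    if missing:
        raise ValueError(f"lineage(s) without taxonomy or override: {missing}")

    divisors = np.empty(len(table.lineage_ids))
    for j, lid in enumerate(table.lineage_ids):
        if lid in overrides:
            d = float(overrides[lid])
        else:
            group = taxonomy.cf_group(lid)
            if group not in cf_map:
                raise ValueError(f"no correction factor for group {group!r} (lineage {lid!r})")
            d = float(cf_map[group])
        if d <= 0:
            raise ValueError(f"non-positive divisor {d} for lineage {lid!r}")
        divisors[j] = d
    data = table.data / divisors
    return AbundanceTable(data, mode="cell")
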