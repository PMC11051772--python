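"""Per-sample trophic indices and depth-layer comparisons.

The trophic index of group g (TI_g, g in {M, A, H}) at a sample is the
relative abundance of that group against the total eukaryotic community T:
TI_M = M/T, TI_A = A/T, TI_H = H/T. The default denominator counts every
retained lineage including trophically unknown ones, so the three indices
sum to at most 1; the ``annotated_only`` convention restricts T to annotated
lineages and makes them sum to exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, EnvTable
from .trophic_annotation import MODES, ModeAssignment

DENOMINATORS = ("all_retained", "annotated_only")
TI_COLUMNS = ("TI_M", "TI_A", "TI_H")


def compute_ti(
    table: AbundanceTable,
    modes: ModeAssignment,
    denominator: str = "all_retained",
) -> pd.DataFrame:
    """Per-sample TI_M, TI_A, TI_H.

    Returns a frame indexed by sample id with the three indices, the
    denominator convention, the abundance mode, and a ``zero_denominator``
    flag (such samples get NaN indices).
    """
    if table.mode not in ("gene", "cell"):
        raise ValueError(f"TI needs a gene or cell table, got mode={table.mode!r}")
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    unknown_modes = [l for l in table.lineage_ids if l not in modes.modes]
    if unknown_modes:
        raise ValueError(f"lineage(s) without a mode assignment: {unknown_modes}")

    values = table.values
    mode_vec = np.array([modes.modes[l] for l in table.lineage_ids])
    group_sums = {g: values[:, mode_vec == g].sum(axis=1) for g in MODES}
    if denominator == "all_retained":
        total = values.sum(axis=1)
    else:
        total = sum(group_sums.values())
    zero = total <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) with zero denominator; TI set to NaN",
            stacklevel=2,
        )
    safe_total = np.where(zero, np.nan, total)
    out = pd.DataFrame(
        {
            "TI_M": group_sums["M"] / safe_total,
            "TI_A": group_sums["A"] / safe_total,
            "TI_H": group_sums["H"] / safe_total,
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
    out["denominator"] = denominator
    out["abundance_mode"] = table.mode
    out["zero_denominator"] = zero
    return out


def aggregate_ti(ti: pd.DataFrame, groups: pd.Series, stat: str = "median") -> pd.DataFrame:
    """Regional summary of indices (median by default, mean also supported)."""
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    joined = ti[list(TI_COLUMNS)].join(groups.rename("group"), how="inner")
    return getattr(joined.groupby("group"), stat)(numeric_only=True)


@dataclass
class PairedLayerResult:
    """Paired surface-vs-CML comparison of one trophic index."""

    index: str
    n_pairs: int
    statistic: float
    p_value: float
    df: int
    median_sur: float
    median_cml: float
    wilcoxon_statistic: float
    wilcoxon_p: float


def compare_layers(ti: pd.DataFrame, env: EnvTable, index: str = "TI_M") -> PairedLayerResult:
    """Paired t-test of an index between SUR and CML samples of a station.

    Pairs are stations contributing both layers; the statistic is positive
    when the surface mean exceeds the CML mean (t on within-station SUR-CML
    differences, df = pairs - 1). A paired Wilcoxon signed-rank test is
    reported alongside as a distribution-free companion.
    """
    if index not in TI_COLUMNS:
        raise ValueError(f"index must be one of {TI_COLUMNS}")
    meta = env.data[["station_id", "layer"]]
    joined = ti[[index]].join(meta, how="inner")
    wide = joined.pivot_table(index="station_id", columns="layer", values=index)
    if "SUR" not in wide.columns or "CML" not in wide.columns:
        raise ValueError("need stations with both SUR and CML samples")
    paired = wide.dropna(subset=["SUR", "CML"])
    n = len(paired)
    if n < 3:
        raise ValueError(f"need >= 3 SUR/CML pairs, got {n}")
    sur = paired["SUR"].to_numpy()
    cml = paired["CML"].to_numpy()
    diff = sur - cml
    if np.allclose(diff, 0.0):
        t_stat, p = 0.0, 1.0
        w_stat, w_p = 0.0, 1.0
    else:
        t = stats.ttest_rel(sur, cml)
        t_stat, p = float(t.statistic), float(t.pvalue)
        w = stats.wilcoxon(sur, cml)
        w_stat, w_p = float(w.statistic), float(w.pvalue)
    return PairedLayerResult(
        index=index,
        n_pairs=n,
        statistic=t_stat,
        p_value=p,
        df=n - 1,
        median_sur=float(np.median(sur)),
        median_cml=float(np.median(cml)),
        wilcoxon_statistic=w_stat,
        wilcoxon_p=w_p,
    )
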