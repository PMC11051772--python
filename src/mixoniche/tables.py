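"""Core tabular containers shared across the pipeline.

Three thin wrappers around :class:`pandas.DataFrame` carry the community
matrix, the ranked taxonomy and the environmental context through the
analysis, each validating the invariants the downstream statistics rely on
(non-negative abundances, unique identifiers, a declared depth layer per
sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Ranks of an 8-level PR2-style taxonomy path, highest to lowest.
PR2_RANKS = (
    "domain",
    "supergroup",
    "division",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Depth layers a sample can come from: surface or chlorophyll-maximum layer.
LAYERS = ("SUR", "CML")

ABUNDANCE_MODES = ("gene", "cell", "hellinger")

#: The curated registry of contextual environmental variables with units.
#: Physical structure, climatology, biogeochemistry and picoplankton stocks;
#: 29 variables in total.
ENV_REGISTRY: Mapping[str, str] = {
    "temperature": "degC",
    "salinity": "PSU",
    "density": "kg m-3",
    "kd_par": "m-1",
    "cml_depth": "m",
    "mld": "m",
    "nitracline_depth": "m",
    "euphotic_depth": "m",
    "par": "mol photons m-2 d-1",
    "sunshine_duration": "h d-1",
    "chl_a": "mg m-3",
    "oxygen": "umol kg-1",
    "no3_no2": "umol L-1",
    "no2": "umol L-1",
    "po4": "umol L-1",
    "sio4": "umol L-1",
    "ph": "total scale",
    "total_alkalinity": "umol kg-1",
    "total_carbon": "umol kg-1",
    "fluorescence": "rfu",
    "poc": "umol kg-1",
    "pic": "umol kg-1",
    "cdom": "ppb",
    "co2": "uatm",
    "npp": "mg C m-2 d-1",
    "iron": "nmol L-1",
    "prochlorococcus": "cells mL-1",
    "synechococcus": "cells mL-1",
    "het_bacteria": "cells mL-1",
}

#: Copy-number correction groups.
CF_GROUPS = ("dinoflagellate", "diatom", "other")


def cf_group_of_path(ranked_path: Iterable[str]) -> str:
    """Derive the copy-number group from a ranked taxonomy path.

    Dinoflagellata lineages carry far more 18S copies per cell than other
    eukaryotes, and diatoms (Bacillariophyta) form a second distinct group;
    everything else is pooled.
    """
    path = set(ranked_path)
    if "Dinoflagellata" in path:
        return "dinoflagellate"
    if "Bacillariophyta" in path:
        return "diatom"
    return "other"


@dataclass
class AbundanceTable:
    """Lineage-by-sample abundance matrix (stored samples x lineages).

    ``mode`` records what the numbers mean: raw 18S gene (read) counts,
    copy-number-corrected cell abundances, or Hellinger-transformed
    compositions.
    """

    data: pd.DataFrame
    mode: str = "gene"

    def __post_init__(self) -> None:
        if self.mode not in ABUNDANCE_MODES:
            raise ValueError(
                f"mode must be one of {ABUNDANCE_MODES}, got {self.mode!r}"
            )
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate lineage ids: {dups}")
        if self.data.size == 0:
            raise ValueError("empty abundance table")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("abundance table contains non-finite values")
        if (values < 0).any():
            raise ValueError("abundance table contains negative values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def lineage_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_lineages(self, keep: Iterable[str]) -> "AbundanceTable":
        keep = [l for l in self.lineage_ids if l in set(keep)]
        return AbundanceTable(self.data[keep].copy(), mode=self.mode)


@dataclass
class TaxonomyTable:
    """Ranked taxonomy for every lineage, with the derived copy-number group.

    ``data`` is indexed by lineage id with the eight PR2-style rank columns
    plus ``phylum`` (the division rank, the level community compositions are
    summarised at) and ``cf_group``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate lineage ids in taxonomy: {dups}")
        missing = [r for r in PR2_RANKS if r not in self.data.columns]
        if missing:
            raise ValueError(f"taxonomy missing rank columns: {missing}")
        if "cf_group" not in self.data.columns:
            self.data = self.data.copy()
            self.data["cf_group"] = [
                cf_group_of_path(row) for row in
                self.data[list(PR2_RANKS)].itertuples(index=False)
            ]
        if "phylum" not in self.data.columns:
            self.data["phylum"] = self.data["division"]

    @classmethod
    def from_paths(cls, paths: Mapping[str, str]) -> "TaxonomyTable":
        """Build from ``lineage_id -> 'rank1;rank2;...;rank8'`` strings."""
        rows = {}
        for lid, path in paths.items():
            parts = [p.strip() for p in str(path).split(";")]
            if len(parts) != len(PR2_RANKS):
                raise ValueError(
                    f"lineage {lid!r}: expected {len(PR2_RANKS)} ranks, "
                    f"got {len(parts)}"
                )
            rows[lid] = parts
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(PR2_RANKS))
        df.index.name = "lineage_id"
        return cls(df)

    @property
    def lineage_ids(self) -> list[str]:
        return list(self.data.index)

    def ranked_path(self, lineage_id: str) -> list[str]:
        return list(self.data.loc[lineage_id, list(PR2_RANKS)])

    def path_string(self, lineage_id: str) -> str:
        return ";".join(self.ranked_path(lineage_id))

    def cf_group(self, lineage_id: str) -> str:
        return str(self.data.loc[lineage_id, "cf_group"])


@dataclass
class EnvTable:
    """Per-sample environmental context.

    ``data`` is indexed by sample id and carries ``station_id``, ``layer``
    and the numeric variable columns. Missing values stay as NaN until
    :func:`mixoniche.data_io.preprocess_env` imputes them; ``meta`` records
    imputation and transform provenance per variable.
    """

    data: pd.DataFrame
    variables: list[str] = field(default_factory=list)
    non_registry: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("station_id", "layer"):
            if col not in self.data.columns:
                raise ValueError(f"env table missing mandatory column {col!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        bad = self.data.loc[~self.data["layer"].isin(LAYERS)]
        if len(bad):
            raise ValueError(
                f"invalid layer for sample(s) {bad.index.tolist()}: "
                f"{bad['layer'].tolist()} (expected one of {LAYERS})"
            )
        if not self.variables:
            self.variables = [
                c for c in self.data.columns if c not in ("station_id", "layer")
            ]
        self.non_registry = [v for v in self.variables if v not in ENV_REGISTRY]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean mask of missing variable cells (True = missing)."""
        return self.data[self.variables].isna()

    def variable_frame(self) -> pd.DataFrame:
        return self.data[self.variables].astype(float)

    def subset_layer(self, layer: str) -> "EnvTable":
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        sub = self.data.loc[self.data["layer"] == layer].copy()
        return EnvTable(sub, variables=list(self.variables), meta=dict(self.meta))
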