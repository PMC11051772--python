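"""Readers, writers and environmental-table preprocessing.

On-disk dialects:

* abundance: TSV, first column ``lineage_id``, remaining columns sample ids
  (lineages as rows, the common metabarcoding layout). A transposed file
  whose first header cell is ``sample_id`` is auto-detected and flipped.
* taxonomy: TSV with columns ``lineage_id`` and a semicolon-delimited
  8-rank path.
* environment: CSV with mandatory ``sample_id,station_id,layer`` columns;
  blank cells or ``NA`` denote missing values.

All writers emit UTF-8 with LF line endings.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tables import ENV_REGISTRY, LAYERS, PR2_RANKS, AbundanceTable, EnvTable, TaxonomyTable

_NA_TOKENS = ("", "NA")


class ParseError(ValueError):
    """A malformed cell or structural defect in an input table."""


def _to_numeric_matrix(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Convert a string frame to floats, naming the first offending cell."""
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & ~df[col].astype(str).str.strip().isin(_NA_TOKENS)
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{what}: cell {df.loc[row, col]!r} at row {row!r}, "
                f"column {col!r} is not numeric"
            )
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def read_abundance(path) -> AbundanceTable:
    """Read a gene-count abundance TSV, auto-detecting orientation."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.empty or raw.shape[1] < 2:
        raise ParseError(f"{path}: empty or single-column abundance table")
    first = raw.columns[0]
    raw = raw.set_index(first)
    if raw.index.duplicated().any():
        dups = sorted(set(raw.index[raw.index.duplicated()]))
        raise ParseError(f"{path}: duplicate {first} entries {dups}")
    mat = _to_numeric_matrix(raw, str(path))
    if first == "sample_id":
        data = mat  # samples already as rows
    else:
        data = mat.T  # lineages as rows on disk (default dialect)
    data.index.name = "sample_id"
    data.columns.name = "lineage_id"
    return AbundanceTable(data, mode="gene")


def write_abundance(table: AbundanceTable, path) -> None:
    out = table.data.T  # lineages as rows on disk
    out.index.name = "lineage_id"
    out.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


def read_taxonomy(path) -> TaxonomyTable:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "lineage_id" not in raw.columns:
        raise ParseError(f"{path}: taxonomy must have a 'lineage_id' column")
    path_col = [c for c in raw.columns if c != "lineage_id"][0]
    if raw["lineage_id"].duplicated().any():
        dups = sorted(set(raw.loc[raw["lineage_id"].duplicated(), "lineage_id"]))
        raise ParseError(f"{path}: duplicate lineage_id {dups}")
    return TaxonomyTable.from_paths(dict(zip(raw["lineage_id"], raw[path_col])))


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("lineage_id\tranked_path\n")
        for lid in taxonomy.lineage_ids:
            fh.write(f"{lid}\t{taxonomy.path_string(lid)}\n")


def read_community_bundle(abundance_path, taxonomy_path):
    """Read the abundance/taxonomy pair and reconcile their lineage universes.

    Returns ``(abundance, taxonomy, unmapped)`` where ``unmapped`` lists
    lineages present in the abundance matrix but absent from the taxonomy.
    """
    abundance = read_abundance(abundance_path)
    taxonomy = read_taxonomy(taxonomy_path)
    unmapped = [l for l in abundance.lineage_ids if l not in set(taxonomy.lineage_ids)]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} lineage(s) missing from taxonomy: {unmapped[:10]}",
            stacklevel=2,
        )
    return abundance, taxonomy, unmapped


def read_env_table(path) -> EnvTable:
    """Read the environmental context CSV; blanks/``NA`` stay missing."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("sample_id", "station_id", "layer"):
        if col not in raw.columns:
            raise ParseError(f"{path}: missing mandatory column {col!r}")
    if raw["sample_id"].duplicated().any():
        dups = sorted(set(raw.loc[raw["sample_id"].duplicated(), "sample_id"]))
        raise ParseError(f"{path}: duplicate sample_id {dups}")
    bad_layer = raw.loc[~raw["layer"].isin(LAYERS)]
    if len(bad_layer):
        raise ParseError(
            f"{path}: invalid layer {bad_layer['layer'].tolist()} for "
            f"sample(s) {bad_layer['sample_id'].tolist()}"
        )
    var_cols = [c for c in raw.columns if c not in ("sample_id", "station_id", "layer")]
    body = raw.set_index("sample_id")
    values = _to_numeric_matrix(body[var_cols].replace(list(_NA_TOKENS), np.nan), str(path))
    data = pd.concat([body[["station_id", "layer"]], values], axis=1)
    env = EnvTable(data, variables=var_cols)
    if env.non_registry:
        warnings.warn(
            f"non-registry environmental variable(s): {env.non_registry}",
            stacklevel=2,
        )
    return env


def write_env_table(env: EnvTable, path) -> None:
    out = env.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, lineterminator="\n", encoding="utf-8")


def preprocess_env(
    env: EnvTable,
    transform: str = "log10",
    standardize: bool = False,
) -> EnvTable:
    """Impute missing values with the column mean, then transform.

    The mean is computed before any transform, so imputation never changes
    a variable's (pre-transform) mean. ``transform`` is ``"log10"`` or
    ``"identity"``. Variables containing non-positive values under a log
    transform are routed to a shifted log, log10(x + eps) with eps equal to
    half the smallest positive observed value; the shift is recorded in
    ``meta['shifts']``. ``standardize`` additionally z-scores every column
    (for PCA input).
    """
    if transform not in ("log10", "identity"):
        raise ValueError(f"unknown transform {transform!r}")
    frame = env.variable_frame().copy()
    all_missing = [v for v in env.variables if frame[v].isna().all()]
    if all_missing:
        raise ValueError(f"variable(s) with no observed values: {all_missing}")

    meta = dict(env.meta)
    meta["imputed_counts"] = {v: int(frame[v].isna().sum()) for v in env.variables}
    frame = frame.fillna(frame.mean())

    shifts: dict[str, float] = {}
    if transform == "log10":
        for v in env.variables:
            col = frame[v].to_numpy()
            if (col <= 0).any():
                positive = col[col > 0]
                if positive.size == 0:
                    raise ValueError(
                        f"variable {v!r} has no positive values; cannot log-transform"
                    )
                eps = 0.5 * float(positive.min())
                shifts[v] = eps
                frame[v] = np.log10(col + eps)
            else:
                frame[v] = np.log10(col)
    meta["transform"] = transform
    meta["shifts"] = shifts

    if standardize:
        sd = frame.std(ddof=1)
        constant = sd.index[(sd == 0) | sd.isna()].tolist()
        if constant:
            raise ValueError(f"constant variable(s) under z-scoring: {constant}")
        frame = (frame - frame.mean()) / sd
        meta["standardized"] = True

    data = pd.concat([env.data[["station_id", "layer"]], frame], axis=1)
    return EnvTable(data, variables=list(env.variables), meta=meta)
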