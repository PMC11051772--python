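import numpy as np
import pandas as pd
import pytest

from mixoniche import AbundanceTable, TaxonomyTable, TrophicAnnotationDB
from mixoniche.tables import EnvTable
from mixoniche.trophic_annotation import ModeAssignment


def make_taxonomy():
    """Five lineages spanning the three copy-number groups and an unknown."""
    return TaxonomyTable.from_paths(
        {
            "L_dino": "Eukaryota;Alveolata;Dinoflagellata;Dinophyceae;"
                      "Gymnodiniales;Kareniaceae;Karlodinium;Karlodinium veneficum",
            "L_hapto": "Eukaryota;Hacrobia;Haptophyta;Prymnesiophyceae;"
                       "Prymnesiales;Chrysochromulinaceae;Chrysochromulina;"
                       "Chrysochromulina_sp_1",
            "L_diatom": "Eukaryota;Stramenopiles;Ochrophyta;Bacillariophyta;"
                        "Bacillariophyta_X;Mediophyceae;Minidiscus;Minidiscus_sp_1",
            "L_mast": "Eukaryota;Stramenopiles;Opalozoa;MAST-4;MAST-4A;"
                      "MAST-4A_X;MAST-4A_XX;MAST-4A_sp.",
            "L_dark": "Eukaryota;Eukaryota_XX;Eukaryota_XXX;Eukaryota_XXXX;"
                      "Eukaryota_XXXXX;Eukaryota_XXXXXX;Eukaryota_X_gen;"
                      "Eukaryota_X_sp.",
        }
    )


def make_db():
    db = TrophicAnnotationDB()
    db.add("Karlodinium veneficum", "species", "M")
    db.add("Chrysochromulina", "genus", "M")
    db.add("Minidiscus_sp_1", "species", "A")
    db.add("MAST-4A_sp.", "species", "H")
    return db


@pytest.fixture
def taxonomy():
    return make_taxonomy()


@pytest.fixture
def annotation_db():
    return make_db()


@pytest.fixture
def gene_table(taxonomy):
    data = pd.DataFrame(
        [[1186.0, 59.3, 105.0, 47.0, 47.0],
         [593.0, 118.6, 210.0, 94.0, 0.0],
         [2372.0, 0.0, 52.5, 23.5, 94.0]],
        index=pd.Index(["S1", "S2", "S3"], name="sample_id"),
        columns=["L_dino", "L_hapto", "L_diatom", "L_mast", "L_dark"],
    )
    return AbundanceTable(data, mode="gene")


@pytest.fixture
def mode_assignment():
    return ModeAssignment(
        modes={"L_dino": "M", "L_hapto": "M", "L_diatom": "A",
               "L_mast": "H", "L_dark": "unknown"},
        resolution_rank={"L_dino": "species", "L_hapto": "genus",
                         "L_diatom": "species", "L_mast": "species",
                         "L_dark": "none"},
    )


def make_env(n_stations=4, layers=("SUR", "CML"), seed=0, variables=None):
    """A small env table with one sample per station and layer."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_stations):
        for layer in layers:
            rows.append(
                {"sample_id": f"ST{i + 1:02d}_{layer}", "station_id": f"ST{i + 1:02d}",
                 "layer": layer}
            )
    df = pd.DataFrame(rows).set_index("sample_id")
    variables = variables or {"par": (20.0, 5.0), "no3_no2": (1.0, 0.5)}
    for var, (mu, sd) in variables.items():
        df[var] = np.abs(rng.normal(mu, sd, len(df))) + 1e-6
    return EnvTable(df)
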