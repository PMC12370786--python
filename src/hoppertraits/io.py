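"""CSV readers and writers for the pipeline's tabular artifacts.

All artifacts are plain CSV.  Communities and feeding matrices are stored in
long (tidy) format on disk and converted to the wide matrices the analysis
functions use.  Column names and units:

specimens.csv   one row per measured individual — species_id, sex,
                body_length_mm, diam_*_mm (4 columns), head_volume_mm3,
                lever_in_mm, lever_out_mm, incisive_region_mm, percent_c,
                percent_n
traits.csv      one row per species — species_id, subfamily,
                body_volume (mm^3), incisor_strength (relative index),
                cn_ratio (mass ratio), n_individuals
communities.csv long — site, period, species_id, count
plants.csv      one row per plant species — plant_species_id,
                functional_group, ldmc (mg/g), sla (mm^2/mg), cn_ratio
feeding.csv     long — individual_id, species_id, subfamily,
                plant_species_id, area_cm2 (multiples of 0.05)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_specimens",
    "write_specimens",
    "read_traits",
    "write_traits",
    "read_communities",
    "write_communities",
    "read_plants",
    "write_plants",
    "read_feeding",
    "write_feeding",
]


def write_specimens(specimens: pd.DataFrame, path: str | Path) -> None:
    specimens.to_csv(path, index=False)


def read_specimens(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, index=True, index_label="species_id")


def read_traits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="species_id")


def write_communities(comm: pd.DataFrame, path: str | Path) -> None:
    """Wide (site, period) x species matrix -> long CSV, zeros dropped."""
    long = (
        comm.stack()
        .rename("count")
        .reset_index()
        .rename(columns={"level_2": "species_id"})
    )
    long = long[long["count"] > 0]
    long.to_csv(path, index=False)


def read_communities(path: str | Path, species: pd.Index | None = None) -> pd.DataFrame:
    """Long CSV -> wide integer matrix with a (site, period) MultiIndex.

    ``species`` optionally fixes the full column set (including species never
    observed) and its order.
    """
    long = pd.read_csv(path)
    wide = (
        long.pivot_table(
            index=["site", "period"],
            columns="species_id",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        .astype(int)
    )
    if species is not None:
        wide = wide.reindex(columns=species, fill_value=0)
    wide.columns.name = "species_id"
    return wide


def write_plants(plants: pd.DataFrame, path: str | Path) -> None:
    plants.to_csv(path, index=True, index_label="plant_species_id")


def read_plants(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="plant_species_id")


def write_feeding(feeding: pd.DataFrame, path: str | Path) -> None:
    """Wide consumption table -> long CSV (zero cells kept: an offered plant
    that was not eaten is information)."""
    meta_cols = [c for c in ("species_id", "subfamily", "no_feeding") if c in feeding]
    plant_cols = [c for c in feeding.columns if c not in meta_cols]
    long = feeding.reset_index().melt(
        id_vars=["individual_id", *meta_cols],
        value_vars=plant_cols,
        var_name="plant_species_id",
        value_name="area_cm2",
    )
    long.drop(columns=["no_feeding"], errors="ignore").to_csv(path, index=False)


def read_feeding(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path)
    meta = (
        long[["individual_id", "species_id", "subfamily"]]
        .drop_duplicates()
        .set_index("individual_id")
    )
    wide = long.pivot(
        index="individual_id", columns="plant_species_id", values="area_cm2"
    ).fillna(0.0)
    out = meta.join(wide)
    out.columns.name = None
    return out
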