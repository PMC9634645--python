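"""CSV readers and writers for the experiment tables.

Files are UTF-8, comma-separated, with a mandatory header row and "."
decimal mark. Readers validate every row against the domain invariants
and report offending rows by (1-based data) row number.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from pollenflow.datamodel import (
    CameraRecord,
    CommunityMatrix,
    DyeObservation,
    GerminationRecord,
    PlantRecord,
    ValidationError,
)

PLANT_COLUMNS = ["plant_id", "population_id", "ecotype", "x", "y", "role",
                 "n_inflorescences", "open_flowers_on_five_infl", "n_flowers_sampled"]
DYE_COLUMNS = ["plant_id", "flower_id", "dye_color", "particle_count"]
CAMERA_COLUMNS = ["population_id", "ecotype", "date", "duration_h",
                  "n_flowers_filmed", "n_flowers_visited", "n_moths"]
GERMINATION_COLUMNS = ["population_id", "ecotype", "n_seeds_plated", "n_germinated",
                       "n_chlorotic", "n_partially_chlorotic"]


class SchemaError(ValueError):
    """A file does not have the required columns."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _build(df: pd.DataFrame, factory, path):
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(factory(row))
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def read_plants(path) -> list[PlantRecord]:
    df = pd.read_csv(path, dtype={"plant_id": str, "population_id": str})
    _require_columns(df, PLANT_COLUMNS, path)

    def factory(row):
        raw = row.open_flowers_on_five_infl
        counts = [] if (isinstance(raw, float) and math.isnan(raw)) or raw == "" else [
            int(tok) for tok in str(raw).split(";")]
        return PlantRecord(
            plant_id=str(row.plant_id), population_id=str(row.population_id),
            ecotype=str(row.ecotype), x=float(row.x), y=float(row.y), role=str(row.role),
            n_inflorescences=int(row.n_inflorescences),
            open_flowers_on_five_infl=counts,
            n_flowers_sampled=int(row.n_flowers_sampled))

    return _build(df, factory, path)


def read_dye_observations(path) -> list[DyeObservation]:
    df = pd.read_csv(path, dtype={"plant_id": str, "flower_id": str})
    _require_columns(df, DYE_COLUMNS, path)
    if df.empty:
        return []
    return _build(df, lambda row: DyeObservation(
        plant_id=str(row.plant_id), flower_id=str(row.flower_id),
        dye_color=str(row.dye_color), particle_count=int(row.particle_count)), path)


def read_community(path) -> CommunityMatrix:
    df = pd.read_csv(path, index_col=0)
    _require_columns(df, ["ecotype", "year"], path)
    return CommunityMatrix.from_frame(df)


def read_cameras(path) -> list[CameraRecord]:
    df = pd.read_csv(path, dtype={"population_id": str, "date": str})
    _require_columns(df, CAMERA_COLUMNS, path)
    return _build(df, lambda row: CameraRecord(
        population_id=str(row.population_id), ecotype=str(row.ecotype), date=str(row.date),
        duration_h=float(row.duration_h), n_flowers_filmed=int(row.n_flowers_filmed),
        n_flowers_visited=int(row.n_flowers_visited), n_moths=int(row.n_moths)), path)


def read_germination(path) -> list[GerminationRecord]:
    df = pd.read_csv(path, dtype={"population_id": str})
    _require_columns(df, GERMINATION_COLUMNS, path)
    return _build(df, lambda row: GerminationRecord(
        population_id=str(row.population_id), ecotype=str(row.ecotype),
        n_seeds_plated=int(row.n_seeds_plated), n_germinated=int(row.n_germinated),
        n_chlorotic=int(row.n_chlorotic),
        n_partially_chlorotic=int(row.n_partially_chlorotic)), path)


def write_plants(plants: Sequence[PlantRecord], path) -> None:
    from pollenflow.datamodel import plants_to_frame
    plants_to_frame(plants).to_csv(path, index=False)


def write_dye_observations(obs: Sequence[DyeObservation], path) -> None:
    pd.DataFrame([vars(o) for o in obs], columns=DYE_COLUMNS).to_csv(path, index=False)


def write_community(m: CommunityMatrix, path) -> None:
    m.to_frame().to_csv(path)


def write_cameras(cams: Sequence[CameraRecord], path) -> None:
    pd.DataFrame([vars(c) for c in cams]).to_csv(path, index=False)


def write_germination(germ: Sequence[GerminationRecord], path) -> None:
    pd.DataFrame([vars(g) for g in germ]).to_csv(path, index=False)


def read_tables(paths: dict) -> dict:
    """Read any subset of the five experiment tables.

    ``paths`` maps table names (``plants``, ``dye``, ``community``,
    ``cameras``, ``germination``) to CSV paths; the result maps the same
    names to typed record collections.
    """
    readers = {"plants": read_plants, "dye": read_dye_observations,
               "community": read_community, "cameras": read_cameras,
               "germination": read_germination}
    unknown = set(paths) - set(readers)
    if unknown:
        raise SchemaError(f"unknown table name(s) {sorted(unknown)}")
    out = {}
    for name, p in paths.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"{name} table not found at {p}")
        out[name] = readers[name](p)
    return out


_EARTH_RADIUS_M = 6_371_000.0


def latlon_to_planar(lat: np.ndarray, lon: np.ndarray,
                     lat0: float | None = None, lon0: float | None = None):
    """Convert geographic degrees to local planar meters.

    Equirectangular projection about (``lat0``, ``lon0``) (defaults:
    centroid); adequate at the few-kilometer extent of a study landscape.
    The analysis layer itself only accepts planar meters.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat0 is None:
        lat0 = float(np.mean(lat))
    if lon0 is None:
        lon0 = float(np.mean(lon))
    x = np.radians(lon - lon0) * _EARTH_RADIUS_M * np.cos(np.radians(lat0))
    y = np.radians(lat - lat0) * _EARTH_RADIUS_M
    return x, y
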