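"""Domain records for the dye-dispersal experiment and their invariants.

Each record type mirrors one table of the field protocol: mapped plants,
per-flower dye observations, derived per-recipient transfer records, the
seed-predator community matrix, camera recordings and germination counts.
Validation happens at construction; readers in :mod:`pollenflow.io`
surface violations with row numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

ECOTYPES = ("Ca", "Si")
ROLES = ("source", "recipient")
DYE_COLORS = ("blue", "pink", "orange", "yellow")
TRANSFER_CLASSES = ("intrapopulation", "intra_ecotypic", "inter_ecotypic")
DIRECTIONS = ("CaToCa", "CaToSi", "SiToCa", "SiToSi")


class ValidationError(ValueError):
    """A record violates a domain invariant."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class PlantRecord:
    """One mapped individual.

    Coordinates are planar projected meters (see
    :func:`pollenflow.io.latlon_to_planar` for a conversion helper); the
    analysis layer never accepts geographic degrees.
    """

    plant_id: str
    population_id: str
    ecotype: str
    x: float
    y: float
    role: str
    n_inflorescences: int = 0
    open_flowers_on_five_infl: list[int] = field(default_factory=list)
    n_flowers_sampled: int = 0

    def __post_init__(self) -> None:
        _check(self.ecotype in ECOTYPES, f"ecotype must be one of {ECOTYPES}, got {self.ecotype!r}")
        _check(self.role in ROLES, f"role must be one of {ROLES}, got {self.role!r}")
        _check(math.isfinite(self.x) and math.isfinite(self.y),
               f"plant {self.plant_id}: non-finite coordinates")
        _check(self.n_inflorescences >= 0, f"plant {self.plant_id}: negative inflorescence count")
        _check(len(self.open_flowers_on_five_infl) <= 5,
               f"plant {self.plant_id}: more than 5 inflorescence flower counts")
        _check(all(c >= 0 for c in self.open_flowers_on_five_infl),
               f"plant {self.plant_id}: negative flower count")
        _check(self.n_flowers_sampled >= 0, f"plant {self.plant_id}: negative flowers sampled")


@dataclass
class DyeObservation:
    """Dye particles of one color on one flower, summed over its three stigmas."""

    plant_id: str
    flower_id: str
    dye_color: str
    particle_count: int

    def __post_init__(self) -> None:
        _check(self.dye_color in DYE_COLORS,
               f"dye_color must be one of {DYE_COLORS}, got {self.dye_color!r}")
        _check(self.particle_count >= 0,
               f"observation ({self.plant_id}, {self.flower_id}, {self.dye_color}): "
               f"negative particle_count {self.particle_count}")


@dataclass
class TransferRecord:
    """One recipient x dye-color pair with distance to source and dye responses."""

    recipient_id: str
    recipient_population: str
    source_population: str
    dye_color: str
    r: float
    mean_count_per_flower: float
    sum_count: int
    n_flowers_sampled: int
    total_flowers_est: float
    transfer_class: str
    direction: str
    n_flowers_with_dye: int = 0
    x: float = float("nan")
    y: float = float("nan")

    def __post_init__(self) -> None:
        _check(self.transfer_class in TRANSFER_CLASSES,
               f"bad transfer_class {self.transfer_class!r}")
        _check(self.direction in DIRECTIONS, f"bad direction {self.direction!r}")
        _check(self.r > 0, f"transfer {self.recipient_id}/{self.dye_color}: r must be > 0")
        _check(self.n_flowers_sampled >= 1,
               f"transfer {self.recipient_id}/{self.dye_color}: no sampled flowers")
        _check(abs(self.sum_count - self.mean_count_per_flower * self.n_flowers_sampled) < 1e-9,
               f"transfer {self.recipient_id}/{self.dye_color}: sum/mean inconsistent")


@dataclass
class CameraRecord:
    """One infrared-camera recording night."""

    population_id: str
    ecotype: str
    date: str
    duration_h: float
    n_flowers_filmed: int
    n_flowers_visited: int
    n_moths: int
    visits_per_h: float = float("nan")
    moths_per_h: float = float("nan")

    def __post_init__(self) -> None:
        _check(self.ecotype in ECOTYPES, f"bad ecotype {self.ecotype!r}")
        _check(self.duration_h > 0, f"camera {self.population_id} {self.date}: duration must be > 0")
        if math.isnan(self.visits_per_h):
            self.visits_per_h = self.n_flowers_visited / self.duration_h
        if math.isnan(self.moths_per_h):
            self.moths_per_h = self.n_moths / self.duration_h
        # printed tables round rates to 2 decimals
        _check(abs(self.visits_per_h - self.n_flowers_visited / self.duration_h) < 0.05,
               f"camera {self.population_id} {self.date}: visits_per_h inconsistent with counts")
        _check(abs(self.moths_per_h - self.n_moths / self.duration_h) < 0.05,
               f"camera {self.population_id} {self.date}: moths_per_h inconsistent with counts")


@dataclass
class GerminationRecord:
    """Germination and chlorosis counts for one population's seed bulk."""

    population_id: str
    ecotype: str
    n_seeds_plated: int
    n_germinated: int
    n_chlorotic: int
    n_partially_chlorotic: int

    def __post_init__(self) -> None:
        _check(self.ecotype in ECOTYPES, f"bad ecotype {self.ecotype!r}")
        _check(0 <= self.n_germinated <= self.n_seeds_plated,
               f"germination {self.population_id}: germinated exceeds plated")
        _check(self.n_chlorotic >= 0 and self.n_partially_chlorotic >= 0,
               f"germination {self.population_id}: negative chlorosis count")
        _check(self.n_chlorotic + self.n_partially_chlorotic <= self.n_germinated,
               f"germination {self.population_id}: chlorotic exceed germinated")


class CommunityMatrix:
    """Population-year x taxon abundance counts with ecotype/year row metadata."""

    def __init__(self, counts: pd.DataFrame, ecotype: Sequence[str], year: Sequence[int]):
        counts = counts.copy()
        _check(not counts.index.duplicated().any(), "duplicated row labels")
        vals = counts.to_numpy()
        _check(np.all(vals >= 0), "negative abundance")
        _check(np.allclose(vals, np.round(vals)), "non-integer abundance")
        _check(len(ecotype) == len(counts) and len(year) == len(counts),
               "row metadata length mismatch")
        _check(all(e in ECOTYPES for e in ecotype), "bad ecotype label in metadata")
        self.counts = counts.astype(int)
        self.ecotype = np.asarray(ecotype, dtype=object)
        self.year = np.asarray(year, dtype=int)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def row_labels(self) -> list[str]:
        return list(self.counts.index)

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "year", self.year)
        out.insert(0, "ecotype", self.ecotype)
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CommunityMatrix":
        meta = {"ecotype", "year"}
        missing = meta - set(df.columns)
        _check(not missing, f"community table missing columns {sorted(missing)}")
        taxa = [c for c in df.columns if c not in meta]
        return cls(df[taxa], df["ecotype"].tolist(), df["year"].tolist())

    def totals_by_ecotype(self) -> pd.DataFrame:
        """Taxon totals summed within each ecotype."""
        return self.counts.groupby(self.ecotype).sum()


def plants_to_frame(plants: Sequence[PlantRecord]) -> pd.DataFrame:
    rows = []
    for p in plants:
        rows.append({
            "plant_id": p.plant_id, "population_id": p.population_id,
            "ecotype": p.ecotype, "x": p.x, "y": p.y, "role": p.role,
            "n_inflorescences": p.n_inflorescences,
            "open_flowers_on_five_infl": ";".join(str(c) for c in p.open_flowers_on_five_infl),
            "n_flowers_sampled": p.n_flowers_sampled,
        })
    return pd.DataFrame(rows)


def transfers_to_frame(transfers: Sequence[TransferRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in transfers])
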