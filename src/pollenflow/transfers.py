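"""Distances, the per-recipient transfer table, and deposition summaries.

The transfer table is the central derived object: one row per recipient
individual x dye color, carrying the distance to the dye source (the
centroid of the marked source group), the mean dye count per flower and
the summed count, plus the transfer classification (intrapopulation,
interpopulation intra-ecotypic, interpopulation inter-ecotypic) and
direction (e.g. Ca source to Si recipient) derived from ecotype labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pollenflow.datamodel import (
    DyeObservation,
    PlantRecord,
    TransferRecord,
    ValidationError,
)


@dataclass(frozen=True)
class DyeSource:
    """A dye color's source population and the planar centroid of its source group."""

    population_id: str
    ecotype: str
    x: float
    y: float


def pairwise_distance(a: PlantRecord, b: PlantRecord) -> float:
    """Euclidean distance in meters between two mapped plants."""
    for p in (a, b):
        if not (math.isfinite(p.x) and math.isfinite(p.y)):
            raise ValueError(f"plant {p.plant_id}: non-finite coordinate")
    return math.hypot(a.x - b.x, a.y - b.y)


def distance_matrix(xy: np.ndarray) -> np.ndarray:
    """All pairwise Euclidean distances for an (n, 2) coordinate array."""
    xy = np.asarray(xy, dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def estimate_total_flowers(p: PlantRecord) -> float:
    """Total open flowers: inflorescence count times mean flowers per counted inflorescence."""
    if not p.open_flowers_on_five_infl:
        raise ValueError(f"plant {p.plant_id}: no inflorescence flower counts recorded")
    if p.n_inflorescences < 1:
        raise ValueError(f"plant {p.plant_id}: n_inflorescences must be >= 1")
    return p.n_inflorescences * float(np.mean(p.open_flowers_on_five_infl))


def classify_transfer(source: DyeSource, recipient: PlantRecord) -> tuple[str, str]:
    direction = f"{source.ecotype}To{recipient.ecotype}"
    if source.population_id == recipient.population_id:
        cls = "intrapopulation"
    elif source.ecotype == recipient.ecotype:
        cls = "intra_ecotypic"
    else:
        cls = "inter_ecotypic"
    return cls, direction


def build_transfer_table(
    plants: Sequence[PlantRecord],
    dye_obs: Sequence[DyeObservation],
    source_map: Mapping[str, DyeSource],
) -> pd.DataFrame:
    """One row per recipient individual x dye color.

    Flowers sampled from a recipient but absent from the dye table for a
    color are scored as zero-count (the protocol scores every collected
    flower). Distance r is recipient to the source-group centroid.
    """
    colors = {o.dye_color for o in dye_obs}
    unmapped = colors - set(source_map)
    if unmapped:
        raise ValidationError(f"dye color(s) {sorted(unmapped)} have no source mapping")

    # summed particles per (plant, color)
    sums: dict[tuple[str, str], int] = {}
    seen: dict[tuple[str, str], set] = {}
    hits: dict[tuple[str, str], set] = {}
    for o in dye_obs:
        key = (o.plant_id, o.dye_color)
        if o.flower_id in seen.setdefault(key, set()):
            raise ValidationError(
                f"duplicate observation for plant {o.plant_id}, flower {o.flower_id}, "
                f"color {o.dye_color}")
        seen[key].add(o.flower_id)
        sums[key] = sums.get(key, 0) + o.particle_count
        if o.particle_count > 0:
            hits.setdefault(key, set()).add(o.flower_id)

    records: list[TransferRecord] = []
    for p in plants:
        if p.role != "recipient":
            continue
        if p.n_flowers_sampled < 1:
            raise ValidationError(f"recipient {p.plant_id} has no sampled flowers")
        total_flowers = (estimate_total_flowers(p)
                         if p.open_flowers_on_five_infl and p.n_inflorescences >= 1
                         else float("nan"))
        for color, src in source_map.items():
            s = sums.get((p.plant_id, color), 0)
            cls, direction = classify_transfer(src, p)
            r = math.hypot(p.x - src.x, p.y - src.y)
            records.append(TransferRecord(
                recipient_id=p.plant_id,
                recipient_population=p.population_id,
                source_population=src.population_id,
                dye_color=color,
                r=r,
                mean_count_per_flower=s / p.n_flowers_sampled,
                sum_count=s,
                n_flowers_sampled=p.n_flowers_sampled,
                total_flowers_est=total_flowers,
                transfer_class=cls,
                direction=direction,
                n_flowers_with_dye=len(hits.get((p.plant_id, color), ())),
                x=p.x, y=p.y,
            ))
    return pd.DataFrame([vars(t) for t in records])


def transfer_summary(transfers: pd.DataFrame) -> pd.DataFrame:
    """Deposition summary per source x recipient population pair.

    For each pair: the percentage of recipient individuals carrying at
    least one particle of the source's dye, and the mean +/- standard
    error (over individuals) of the per-individual percentage of sampled
    flowers carrying dye.
    """
    rows = []
    grouped = transfers.groupby(["source_population", "recipient_population"], sort=True)
    for (src, rec), g in grouped:
        n = len(g)
        with_dye = (g["sum_count"] >= 1).sum()
        flower_pct = 100.0 * g["n_flowers_with_dye"] / g["n_flowers_sampled"]
        se = flower_pct.std(ddof=1) / math.sqrt(n) if n > 1 else float("nan")
        rows.append({
            "source_population": src,
            "recipient_population": rec,
            "transfer_class": g["transfer_class"].iloc[0],
            "n_recipients": n,
            "pct_individuals_with_dye": 100.0 * with_dye / n,
            "mean_pct_flowers_with_dye": flower_pct.mean(),
            "se_pct_flowers_with_dye": se,
        })
    return pd.DataFrame(rows)
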