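"""Loaders for the published summary tables shipped with the package.

These are transcriptions of the printed result tables of the *Silene
nutans* dye-dispersal study: the seed-predator abundance matrix
(population-year x five taxonomic groups), the infrared-camera
recording log, and the per-population kernel-fit summary (Moran's I,
alpha, beta, delta_k, Gamma correlation). They carry only in-paper
summary data — the underlying raw observations are not included.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from pollenflow.datamodel import CameraRecord, CommunityMatrix


def _data_path(name: str):
    return resources.files("pollenflow.data").joinpath(name)


def load_seed_predators() -> CommunityMatrix:
    """The 13-row x 5-taxon seed-predator abundance matrix."""
    with resources.as_file(_data_path("table2_seed_predators.csv")) as p:
        df = pd.read_csv(p, index_col="row_label")
    return CommunityMatrix.from_frame(df)


def load_cameras() -> list[CameraRecord]:
    """Camera recording nights; rates recomputed from counts and duration."""
    with resources.as_file(_data_path("table3_cameras.csv")) as p:
        df = pd.read_csv(p)
    return [CameraRecord(
        population_id=r.population_id, ecotype=r.ecotype, date=r.date,
        duration_h=float(r.duration_h), n_flowers_filmed=int(r.n_flowers_filmed),
        n_flowers_visited=int(r.n_flowers_visited), n_moths=int(r.n_moths))
        for r in df.itertuples(index=False)]


def load_cameras_frame() -> pd.DataFrame:
    recs = load_cameras()
    return pd.DataFrame([vars(c) for c in recs])


def load_kernel_summary() -> pd.DataFrame:
    """Published per-population kernel and spatial-autocorrelation summary.

    The row without kernel entries is the population for which no fit
    converged; the two rows with alpha = 1e-4 are the degenerate
    boundary fits whose mean transfer distances the study itself flags
    as questionable.
    """
    with resources.as_file(_data_path("table4_kernel_fits.csv")) as p:
        return pd.read_csv(p)
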