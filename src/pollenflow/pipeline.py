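"""End-to-end orchestration from a run manifest.

A manifest (YAML mapping or dict) names the input CSV tables, the
dye-color -> source mapping, analysis toggles and options. ``run_all``
executes every enabled stage, isolating stage failures so the
independent stages still complete, and writes all outputs as CSV plus a
plain-text log with seeds, versions and the parameter echo.

A single global seed is expanded into per-stage seeds by a fixed
scheme (stable hash of the stage name added to the global seed, modulo
2**31) so stage-level reruns reproduce full-pipeline runs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pollenflow import io as pio
from pollenflow.datamodel import CommunityMatrix
from pollenflow.transfers import DyeSource, build_transfer_table, transfer_summary
from pollenflow.kernel import fit_kernel, gamma_correlation
from pollenflow.spatial import inverse_distance_weights, moran_permutation_test
from pollenflow.hurdle import ANALYSES, run_transfer_analyses
from pollenflow.community import mann_whitney_u, chisq_two_proportions, pca_correlation, permanova

STAGES = ("transfer_summary", "kernel", "moran", "hurdle", "community", "germination")


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) + zlib.adler32(stage.encode())) % (2 ** 31)


@dataclass
class RunManifest:
    paths: dict
    source_map: dict          # dye_color -> {population_id, ecotype, x, y}
    out_dir: str = "results"
    seed: int = 0
    analyses: list = field(default_factory=lambda: list(STAGES))
    exclude: dict = field(default_factory=dict)   # analysis name -> recipient ids
    options: dict = field(default_factory=dict)   # objective, family, distance, n_perm

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def sources(self) -> dict[str, DyeSource]:
        return {color: DyeSource(**spec) for color, spec in self.source_map.items()}


def run_all(manifest: RunManifest) -> dict:
    """Run every enabled stage; returns {stage: result or error string}."""
    out_dir = Path(manifest.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    opts = manifest.options
    n_perm = int(opts.get("n_perm", 999))
    log_lines = [f"pollenflow run; global seed = {manifest.seed}",
                 f"numpy {np.__version__}, pandas {pd.__version__}",
                 f"options: {opts}"]
    results: dict = {}

    tables = pio.read_tables(manifest.paths)
    plants = tables.get("plants", [])
    dye = tables.get("dye", [])
    transfers = None
    if plants:
        transfers = build_transfer_table(plants, dye, manifest.sources())
        transfers.to_csv(out_dir / "transfer_table.csv", index=False)

    def _stage(name, fn):
        if name not in manifest.analyses:
            return
        try:
            results[name] = fn()
            log_lines.append(f"stage {name}: ok (seed {stage_seed(manifest.seed, name)})")
        except Exception as exc:  # keep independent stages running
            results[name] = f"error: {exc}"
            log_lines.append(f"stage {name}: FAILED: {exc}")

    def _summary():
        summ = transfer_summary(transfers)
        summ.to_csv(out_dir / "transfer_summary.csv", index=False)
        return summ

    def _kernel():
        rows = []
        for pop, g in transfers[transfers["transfer_class"] == "intrapopulation"
                                ].groupby("recipient_population"):
            fit = fit_kernel(g["r"].to_numpy(), g["mean_count_per_flower"].to_numpy(),
                             objective=opts.get("objective", "chisq"))
            gam = gamma_correlation(g["mean_count_per_flower"].to_numpy(),
                                    g["r"].to_numpy())
            w = inverse_distance_weights(g[["x", "y"]].to_numpy())
            mi = moran_permutation_test(g["mean_count_per_flower"].to_numpy(), w,
                                        n_perm=n_perm,
                                        seed=stage_seed(manifest.seed, "kernel"))
            rows.append({"population": pop, "morans_I": mi.I, "morans_p": mi.p_perm,
                         "alpha": fit.alpha, "beta": fit.beta, "delta_k": fit.delta_k,
                         "boundary_flag": fit.boundary_flag,
                         "gamma": gam.gamma, "gamma_p": gam.p_value})
        table = pd.DataFrame(rows)
        table.to_csv(out_dir / "kernel_table.csv", index=False)
        return table

    def _moran():
        rows = []
        for color, g in transfers.groupby("dye_color"):
            if g["mean_count_per_flower"].nunique() < 2 or len(g) < 3:
                continue
            w = inverse_distance_weights(g[["x", "y"]].to_numpy())
            mi = moran_permutation_test(g["mean_count_per_flower"].to_numpy(), w,
                                        n_perm=n_perm,
                                        seed=stage_seed(manifest.seed, "moran"))
            rows.append({"dye_color": color, "I": mi.I, "p_perm": mi.p_perm,
                         "n": len(g)})
        table = pd.DataFrame(rows)
        table.to_csv(out_dir / "moran_by_color.csv", index=False)
        return table

    def _hurdle():
        out = {}
        frames = []
        for which in ANALYSES:
            try:
                fit, tidy, moran = run_transfer_analyses(
                    transfers, which, family=opts.get("family", "negbin"),
                    exclude=manifest.exclude.get(which),
                    seed=stage_seed(manifest.seed, "hurdle"))
                tidy.insert(0, "analysis", which)
                if moran is not None:
                    tidy["residual_moran_I"] = moran.I
                    tidy["residual_moran_p"] = moran.p_perm
                frames.append(tidy)
                out[which] = fit
            except ValueError as exc:
                out[which] = f"error: {exc}"
        if frames:
            pd.concat(frames).to_csv(out_dir / "hurdle_coefficients.csv", index=False)
        if all(isinstance(v, str) for v in out.values()):
            raise ValueError("; ".join(str(v) for v in out.values()))
        return out

    def _community():
        out = {}
        if "community" in tables:
            m: CommunityMatrix = tables["community"]
            pca = pca_correlation(m)
            pca.scores.to_csv(out_dir / "pca_scores.csv")
            pca.variable_axis_correlations.to_csv(out_dir / "pca_variable_correlations.csv")
            perm = permanova(m, distance=opts.get("distance", "bray_curtis"),
                             n_perm=n_perm, seed=stage_seed(manifest.seed, "community"))
            perm.table.to_csv(out_dir / "permanova.csv", index=False)
            out["pca"] = pca
            out["permanova"] = perm
        if "cameras" in tables:
            cams = pd.DataFrame([vars(c) for c in tables["cameras"]])
            rows = []
            for var in ("duration_h", "n_flowers_filmed", "moths_per_h", "visits_per_h"):
                si = cams.loc[cams["ecotype"] == "Si", var]
                ca = cams.loc[cams["ecotype"] == "Ca", var]
                u = mann_whitney_u(si, ca)
                rows.append({"variable": var, "U_si": u.U_first, "p": u.p_two_sided})
            mw = pd.DataFrame(rows)
            mw.to_csv(out_dir / "mann_whitney.csv", index=False)
            out["mann_whitney"] = mw
        return out

    def _germination():
        germ = pd.DataFrame([vars(g) for g in tables["germination"]])
        by = germ.groupby("ecotype")[["n_seeds_plated", "n_germinated",
                                      "n_chlorotic", "n_partially_chlorotic"]].sum()
        g = chisq_two_proportions(by.loc["Ca", "n_germinated"], by.loc["Ca", "n_seeds_plated"],
                                  by.loc["Si", "n_germinated"], by.loc["Si", "n_seeds_plated"])
        chl_ca = by.loc["Ca", "n_chlorotic"] + by.loc["Ca", "n_partially_chlorotic"]
        chl_si = by.loc["Si", "n_chlorotic"] + by.loc["Si", "n_partially_chlorotic"]
        c = chisq_two_proportions(chl_ca, by.loc["Ca", "n_germinated"],
                                  chl_si, by.loc["Si", "n_germinated"])
        table = pd.DataFrame([
            {"test": "germination", "chi2": g.statistic, "df": g.df, "p": g.p},
            {"test": "chlorosis", "chi2": c.statistic, "df": c.df, "p": c.p}])
        table.to_csv(out_dir / "germination_tests.csv", index=False)
        return table

    if transfers is not None:
        _stage("transfer_summary", _summary)
        _stage("kernel", _kernel)
        _stage("moran", _moran)
        _stage("hurdle", _hurdle)
    if "community" in tables or "cameras" in tables:
        _stage("community", _community)
    if "germination" in tables:
        _stage("germination", _germination)

    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return results


def validate(seed: int = 0) -> dict[str, bool]:
    """Reduced-replicate internal consistency suites; {suite: passed}.

    Cheap spot checks of the heavy invariants covered in full by the
    test suite: kernel normalization, closed-form vs numerical mean
    distance, Moran brute-force equivalence, and the hurdle likelihood
    separation on a small synthetic fit.
    """
    from scipy.integrate import quad
    from pollenflow.kernel import kernel_density, mean_dispersal_distance
    from pollenflow.spatial import morans_i
    from pollenflow.synthetic import SimConfig, simulate_landscape, \
        simulate_dye_deposition, default_source_map
    from pollenflow.hurdle import HurdleSpec, fit_hurdle

    out = {}
    norm_ok, moment_ok = True, True
    for a in (0.5, 30.0):
        for b in (0.5, 1.0, 2.0):
            total = quad(lambda r: kernel_density(a, b, r) * 2 * np.pi * r,
                         0, np.inf, limit=200)[0]
            norm_ok &= abs(total - 1) < 1e-6
            mom = quad(lambda r: r * kernel_density(a, b, r) * 2 * np.pi * r,
                       0, np.inf, limit=200)[0]
            moment_ok &= abs(mom - mean_dispersal_distance(a, b)) / mom < 1e-6
    out["kernel_normalization"] = norm_ok
    out["mean_distance_closed_form"] = moment_ok

    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 100, (12, 2))
    vals = rng.normal(size=12)
    w = inverse_distance_weights(coords)
    if not np.allclose(np.diag(w), 0.0):
        out["moran_weights"] = False
    else:
        out["moran_weights"] = True
    z = vals - vals.mean()
    brute = sum(w[i, j] * z[i] * z[j] for i in range(12) for j in range(12))
    brute = 12 / w.sum() * brute / np.sum(z ** 2)
    out["moran_brute_force"] = abs(brute - morans_i(vals, w)) < 1e-10

    cfg = SimConfig(plants_per_population=20, seed=seed)
    plants = simulate_landscape(cfg)
    dye = simulate_dye_deposition(plants, cfg)
    tr = build_transfer_table(plants, dye, default_source_map(cfg, plants))
    intra = tr[tr["transfer_class"] == "intrapopulation"].reset_index(drop=True)
    fit = fit_hurdle(intra, HurdleSpec(zero_formula="r", count_formula="r"), seed=seed)
    out["hurdle_loglik_separates"] = bool(
        abs(fit.loglik - (fit.loglik_zero + fit.loglik_count)) < 1e-8)
    return out
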