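"""End-to-end driver: synthetic inputs through every analysis stage.

One call generates (or loads) the inputs, runs superimposition, both
ordinations, the consensus-guild pipeline with sub-clustering, disparity
through time, NPMANOVA between bins, and assemblage summaries, and
writes every product as CSV/JSON into an output directory.  Output is
deterministic for a fixed config and master seed.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import assemblage_ecology as ae
from . import disparity_time as dt
from . import guild_clustering as gc
from . import synthetic_data as synth
from .functional_characters import z_standardize
from .gpa_shape import gpa_align
from .io_formats import default_timebins, write_results, write_tps
from .ordination import pca, pc_contributions

logger = logging.getLogger("guildspace.pipeline")

DEFAULTS = {
    "n_taxa": 136,
    "n_guilds": 5,
    "separation": 6.0,
    "fidelity": 0.9,
    "k_range": [4, 10],
    "sub_k_range": [2, 6],
    "gap_B": 100,
    "boot_B": 1000,
    "n_perm": 999,
    "n_assemblages": 12,
    "planted_conflict_pairs": 0,
    "seed": 0,
}


def run_pipeline(config: dict | None = None, outdir: str | Path = "out") -> dict:
    """Run every stage on synthetic data and write all products.

    Returns a summary dict of the headline numbers (variance fractions,
    chosen k, guild counts, conflict totals).
    """
    cfg = {**DEFAULTS, **(config or {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    rng = np.random.default_rng(master)
    t0 = time.perf_counter()

    scfg = synth.SyntheticConfig(
        n_taxa=int(cfg["n_taxa"]), n_guilds=int(cfg["n_guilds"]),
        separation=float(cfg["separation"]), fidelity=float(cfg["fidelity"]),
        n_assemblages=int(cfg["n_assemblages"]),
        planted_conflict_pairs=int(cfg["planted_conflict_pairs"]),
        seed=master,
    )
    chars, truth, clades = synth.generate_functional_table(scfg, rng)
    shapes, shape_truth = synth.generate_shape_set(scfg, rng)
    bins = default_timebins()
    taxa, assem_table = synth.generate_ranges_and_assemblages(
        scfg, rng, guilds=truth, clades=clades, bins=bins)
    write_tps(outdir / "landmarks.tps", shapes)
    write_results(taxa, outdir / "taxa.csv")
    write_results(assem_table, outdir / "assemblages.csv")
    logger.info("synthesis done in %.1fs", time.perf_counter() - t0)

    # --- shape: GPA + PCA ---
    aligned = gpa_align(shapes, slide=True)
    flat = pd.DataFrame(aligned.flat(), index=aligned.specimen_ids)
    write_results(flat.reset_index(names="taxon_id"),
                  outdir / "aligned_coords.csv")
    shape_pca = pca(flat)
    write_results(shape_pca.scores.reset_index(names="taxon_id"),
                  outdir / "shape_scores.csv")
    # --- function: z-score + PCA ---
    sfmd, zparams = z_standardize(chars)
    write_results(sfmd.reset_index(), outdir / "sfmd.csv")
    write_results(zparams.reset_index(names="character"),
                  outdir / "z_params.csv")
    func_pca = pca(sfmd)
    write_results(func_pca.scores.reset_index(names="taxon_id"),
                  outdir / "functional_scores.csv")
    variance = pd.DataFrame({
        "space": ["shape"] * len(shape_pca.variance_fractions)
        + ["function"] * len(func_pca.variance_fractions),
        "axis": [f"PC{i+1}" for i in range(len(shape_pca.variance_fractions))]
        + [f"PC{i+1}" for i in range(len(func_pca.variance_fractions))],
        "fraction": np.concatenate([shape_pca.variance_fractions,
                                    func_pca.variance_fractions]),
    })
    write_results(variance, outdir / "variance_fractions.csv")
    contrib = pd.DataFrame({
        "character": func_pca.loadings.index,
        "fPC1": pc_contributions(func_pca, 0).values,
        "fPC2": pc_contributions(func_pca, 1).values,
    })
    write_results(contrib, outdir / "pc_contributions.csv")
    logger.info("ordination done in %.1fs", time.perf_counter() - t0)

    # --- guilds ---
    guilds, gaps, parts = gc.run_guild_pipeline(
        sfmd, k_range=tuple(cfg["k_range"]), B=int(cfg["gap_B"]),
        seed=int(rng.integers(2**31)))
    big = guilds.table["ffg"].value_counts().idxmax()
    try:
        guilds = gc.subcluster_guild(
            guilds, big, sfmd, k_range=tuple(cfg["sub_k_range"]),
            B=int(cfg["gap_B"]), seed=int(rng.integers(2**31)))
    except ValueError as e:
        logger.warning("sub-clustering skipped: %s", e)
    write_results(guilds.to_frame(), outdir / "guilds.csv")
    gap_rows = [{"method": m, "k": int(k), "gap": g, "se": s}
                for m, curve in gaps.items()
                for k, g, s in zip(curve.k_values, curve.gap, curve.se)]
    write_results(pd.DataFrame(gap_rows), outdir / "gap_curves.csv")
    clade_map = gc.assign_clade_guilds(guilds, clades)
    write_results(clade_map, outdir / "clade_guilds.json")
    d_sfmd = gc.euclidean_distance_matrix(sfmd)
    val_rows = []
    for p in parts:
        _, _, mean_sil = gc.silhouette_widths(d_sfmd, p)
        ext = gc.external_validation(p, clades)
        val_rows.append({"method": p.method, "k": p.k,
                         "mean_silhouette": mean_sil, **ext})
    write_results(pd.DataFrame(val_rows), outdir / "validation.csv")
    logger.info("clustering done in %.1fs", time.perf_counter() - t0)

    # --- disparity through time ---
    membership = dt.bin_taxa(taxa[taxa["diet"] == "herbivore"], bins)
    d_shape = gc.DistanceMatrix(
        list(flat.index),
        np.linalg.norm(flat.values[:, None] - flat.values[None], axis=2))
    disp_rows = []
    for bin_name, sub in membership.groupby("bin", observed=False):
        members = [t for t in sub["taxon_id"] if t in flat.index]
        row = dt.disparity_mpd(d_shape, members, B=int(cfg["boot_B"]),
                               seed=int(rng.integers(2**31)))
        disp_rows.append({"bin": bin_name, "clade": "all", "metric": "MPD",
                          **row})
        for metric in ("sum_of_variances", "procrustes_variance"):
            space = flat if metric == "procrustes_variance" else sfmd
            ok = [t for t in members if t in space.index]
            v = dt.variance_disparity(space, ok, metric) if len(ok) >= 2 \
                else {"estimate": np.nan, "n_taxa": len(ok)}
            disp_rows.append({"bin": bin_name, "clade": "all",
                              "metric": metric, **v})
    write_results(pd.DataFrame(disp_rows), outdir / "disparity.csv")

    # NPMANOVA between epochs (first-appearance grouping keeps taxa unique)
    fa_epoch = taxa[taxa["diet"] == "herbivore"].set_index("taxon_id")[
        "first_bin"].map(lambda b: bins.epoch_of(b))
    counts = fa_epoch.value_counts()
    keep = fa_epoch[fa_epoch.isin(counts[counts >= 2].index)]
    if keep.nunique() >= 2:
        ids = [t for t in keep.index if t in flat.index]
        perm = dt.pairwise_npmanova(
            d_shape.submatrix(ids), keep.loc[ids],
            n_perm=int(cfg["n_perm"]), seed=int(rng.integers(2**31)))
        write_results(perm, outdir / "npmanova_epoch.csv")
    hulls = dt.timeslice_occupancy(shape_pca.scores, membership)
    write_results(hulls, outdir / "timeslice_hulls.csv")
    logger.info("disparity done in %.1fs", time.perf_counter() - t0)

    # --- assemblages ---
    assemblages = ae.assemblages_from_table(assem_table, taxa)
    taxonomy = taxa.set_index("taxon_id")["clade"]
    summaries = [ae.assemblage_summaries(a, taxonomy) for a in assemblages]
    write_results({s["locality"]: s for s in summaries},
                  outdir / "assemblage_summaries.json")
    reports = []
    for res in ("FFG", "FFsG"):
        for a in assemblages:
            reports.append(ae.count_ffg_conflicts(
                a, guilds, res, clade_guilds=clade_map, taxonomy=taxonomy))
    write_results(ae.conflict_table(reports), outdir / "conflicts.csv")
    logger.info("pipeline complete in %.1fs", time.perf_counter() - t0)

    ffg_conf = sum(r.n_conflicts for r in reports if r.resolution == "FFG")
    ffsg_conf = sum(r.n_conflicts for r in reports if r.resolution == "FFSG")
    return {
        "n_taxa": int(cfg["n_taxa"]),
        "shape_pc1_pct": 100.0 * float(shape_pca.variance_fractions[0]),
        "shape_pc2_pct": 100.0 * float(shape_pca.variance_fractions[1]),
        "func_pc1_pct": 100.0 * float(func_pca.variance_fractions[0]),
        "func_pc2_pct": 100.0 * float(func_pca.variance_fractions[1]),
        "chosen_k": int(parts[0].k),
        "n_ffg": int(guilds.table["ffg"].nunique()),
        "n_ffsg": int(guilds.table.loc[guilds.table["ffsg"] != "",
                                       "ffsg"].nunique()),
        "n_inconsistent": len(guilds.inconsistent),
        "ffg_conflicts": int(ffg_conf),
        "ffsg_conflicts": int(ffsg_conf),
        "truth": truth,
        "guilds": guilds,
    }
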