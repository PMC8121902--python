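"""Time-binned disparity, PERMANOVA between bins, and morphospace slices.

Taxa are binned range-through (present in every bin between first and
last appearance).  Disparity per bin (optionally per clade) comes in
three flavours reported side by side: mean pairwise Euclidean distance
(MPD) with bootstrap percentile CIs, the trace of the covariance matrix
(sum of variances), and Procrustes variance (mean squared distance to
the mean shape).  Shifts in morphospace occupation between bins are
tested with a one-way NPMANOVA (distance-based pseudo-F, permutation p),
with Bonferroni correction over pairwise comparisons.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .io_formats import TimeBinScheme
from .guild_clustering import DistanceMatrix

logger = logging.getLogger("guildspace.disparity")

__all__ = [
    "bin_taxa",
    "disparity_mpd",
    "variance_disparity",
    "npmanova",
    "pairwise_npmanova",
    "centroid_divergence",
    "timeslice_occupancy",
]


def bin_taxa(taxa: pd.DataFrame, bins: TimeBinScheme) -> pd.DataFrame:
    """Range-through bin membership: one row per (bin, taxon).

    Returns columns ``bin, taxon_id, clade`` ordered by the bin scheme.
    """
    rows = []
    for rec in taxa.itertuples(index=False):
        for b in bins.span(rec.first_bin, rec.last_bin):
            rows.append((b, rec.taxon_id, rec.clade))
    out = pd.DataFrame(rows, columns=["bin", "taxon_id", "clade"])
    out["bin"] = pd.Categorical(out["bin"], categories=bins.names, ordered=True)
    return out.sort_values(["bin", "taxon_id"], ignore_index=True)


def disparity_mpd(
    d: DistanceMatrix,
    members: list[str],
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """Mean pairwise distance among ``members`` with bootstrap 95% CI.

    The bootstrap resamples taxa with replacement; pairs drawing the same
    original taxon twice are excluded from the resampled mean.  Bins with
    fewer than two members yield missing estimates.
    """
    pos = {t: i for i, t in enumerate(d.ids)}
    try:
        idx = np.asarray([pos[t] for t in members])
    except KeyError as e:
        raise KeyError(f"taxon not in distance matrix: {e}") from None
    n = len(idx)
    if n < 2:
        logger.info("MPD skipped: %d member(s)", n)
        return {"estimate": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                "n_taxa": n, "n_boot": 0}
    sub = d.matrix[np.ix_(idx, idx)]
    iu = np.triu_indices(n, k=1)
    est = float(sub[iu].mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(B)
    for b in range(B):
        take = rng.integers(0, n, size=n)
        rs = sub[np.ix_(take, take)][iu]
        distinct = take[iu[0]] != take[iu[1]]
        boots[b] = rs[distinct].mean() if distinct.any() else np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return {"estimate": est, "ci_lo": float(lo), "ci_hi": float(hi),
            "n_taxa": n, "n_boot": B}


def variance_disparity(
    data: pd.DataFrame,
    members: list[str],
    metric: str = "sum_of_variances",
) -> dict:
    """Variance-based disparity of ``members`` in a coordinate space.

    ``sum_of_variances`` is the trace of the sample (n-1) covariance;
    ``procrustes_variance`` is the mean squared distance to the member
    mean (1/n).  Both are invariant to translation of the space.
    """
    if metric not in ("sum_of_variances", "procrustes_variance"):
        raise ValueError(f"unknown metric {metric!r}")
    x = data.loc[members].to_numpy(dtype=float)
    n = len(x)
    if n < 2:
        return {"estimate": np.nan, "n_taxa": n}
    centred = x - x.mean(axis=0)
    sq = (centred ** 2).sum()
    if metric == "sum_of_variances":
        est = sq / (n - 1)
    else:
        est = sq / n
    return {"estimate": float(est), "n_taxa": n}


def _ss_partition(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Total and within-group sums of squared distances (Gower partition)."""
    n = len(d2)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in np.unique(labels):
        mask = labels == g
        ng = mask.sum()
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    return float(ss_total), float(ss_within)


def npmanova(
    d: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 9999,
    seed: int = 0,
) -> dict:
    """One-way NPMANOVA on a distance matrix.

    pseudo-F = (SS_among/(g−1)) / (SS_within/(n−g)) from the distance-
    based sum-of-squares partition; p = (1 + #{F_perm ≥ F_obs}) /
    (1 + n_perm) over random label permutations.
    """
    labels = groups.loc[d.ids].to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"group(s) with fewer than two members: {small}")
    d2 = d.matrix ** 2
    n, g = len(labels), len(uniq)
    ss_total, ss_within = _ss_partition(d2, labels)
    ss_among = ss_total - ss_within
    f_obs = (ss_among / (g - 1)) / (ss_within / (n - g))

    # permutations: SS_within for permuted labels via 0/1 membership
    # masks, vectorised over permutation batches
    rng = np.random.default_rng(seed)
    codes = np.searchsorted(uniq, labels)
    exceed = 0
    chunk = 512
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.empty((b, n), dtype=int)
        for i in range(b):
            perms[i] = rng.permutation(codes)
        masks = np.zeros((b, g, n))
        rows = np.repeat(np.arange(b), n)
        masks[rows, perms.ravel(), np.tile(np.arange(n), b)] = 1.0
        within = np.einsum("bgi,ij,bgj->bg", masks, d2, masks) / (2.0 * counts)
        ss_w = within.sum(axis=1)
        f_perm = ((ss_total - ss_w) / (g - 1)) / (ss_w / (n - g))
        exceed += int((f_perm >= f_obs - 1e-12).sum())
        done += b
    p = (1.0 + exceed) / (1.0 + n_perm)
    return {"pseudo_F": float(f_obs), "p": float(p), "n_perm": n_perm,
            "n": n, "n_groups": g}


def pairwise_npmanova(
    d: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """All group-pair NPMANOVAs with Bonferroni-adjusted p-values.

    Pairs involving a group with fewer than two members are skipped with
    a log entry; the Bonferroni factor is the number of tests actually
    run.
    """
    labels = groups.loc[d.ids]
    uniq = sorted(labels.unique(), key=str)
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(uniq, 2):
        ids = [t for t in d.ids if labels[t] in (a, b)]
        sub_labels = labels.loc[ids]
        if (sub_labels == a).sum() < 2 or (sub_labels == b).sum() < 2:
            logger.info("pairwise NPMANOVA skipped for (%s, %s): group too small",
                        a, b)
            continue
        res = npmanova(d.submatrix(ids), sub_labels, n_perm,
                       seed=int(rng.integers(2**31)))
        rows.append({"group_a": a, "group_b": b,
                     "pseudo_F": res["pseudo_F"], "p": res["p"]})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def centroid_divergence(
    scores: pd.DataFrame,
    taxonomy: pd.Series,
    membership: pd.DataFrame,
    clades: tuple[str, str],
) -> pd.DataFrame:
    """Per-bin Euclidean distance between two clades' mean vectors.

    Bins where either clade is absent get a missing distance.
    """
    a, b = clades
    rows = []
    for bin_name, sub in membership.groupby("bin", observed=False):
        taxa_a = [t for t in sub["taxon_id"]
                  if t in taxonomy.index and taxonomy[t] == a and t in scores.index]
        taxa_b = [t for t in sub["taxon_id"]
                  if t in taxonomy.index and taxonomy[t] == b and t in scores.index]
        if not taxa_a or not taxa_b:
            rows.append({"bin": bin_name, "distance": np.nan,
                         "n_a": len(taxa_a), "n_b": len(taxa_b)})
            continue
        mu_a = scores.loc[taxa_a].mean(axis=0).to_numpy()
        mu_b = scores.loc[taxa_b].mean(axis=0).to_numpy()
        rows.append({"bin": bin_name,
                     "distance": float(np.linalg.norm(mu_a - mu_b)),
                     "n_a": len(taxa_a), "n_b": len(taxa_b)})
    return pd.DataFrame(rows)


def timeslice_occupancy(
    scores: pd.DataFrame,
    membership: pd.DataFrame,
) -> pd.DataFrame:
    """Convex hull vertices and area per clade per bin on PC1–PC2.

    Fewer than three (or collinear) points give a degenerate hull of
    area 0 whose vertex list is the points themselves.
    """
    pts2 = scores.iloc[:, :2]
    rows = []
    for (bin_name, clade), sub in membership.groupby(["bin", "clade"],
                                                     observed=False):
        taxa = [t for t in sub["taxon_id"] if t in pts2.index]
        if not taxa:
            continue
        p = pts2.loc[taxa].to_numpy(dtype=float)
        area, verts = _hull(p)
        rows.append({"bin": bin_name, "clade": clade, "n_taxa": len(taxa),
                     "area": area,
                     "vertices": ";".join(f"{x:.10g},{y:.10g}" for x, y in verts)})
    return pd.DataFrame(rows)


def _hull(p: np.ndarray) -> tuple[float, np.ndarray]:
    if len(p) < 3:
        return 0.0, p
    try:
        h = ConvexHull(p)
    except QhullError:  # collinear
        order = np.lexsort((p[:, 1], p[:, 0]))
        return 0.0, p[[order[0], order[-1]]]
    return float(h.volume), p[h.vertices]
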