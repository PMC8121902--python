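"""Functional feeding groups by consensus clustering of the SFMD.

Three unsupervised methods — agglomerative hierarchical (Ward), K-means
and partitioning around medoids (PAM) — are run on the Euclidean
distance structure of the z-scored functional characters.  The number of
clusters is chosen from a configured range (default 4–10) by the gap
statistic with a uniform reference drawn in the principal-axis-aligned
bounding box of the data.  Taxa on which all three methods agree (after
label matching) form the core feeding guilds (FFGs); disagreeing taxa
are flagged inconsistent and, for reporting, attached to the guild of
their nearest core neighbour in SFMD space.  The same machinery re-run
inside one guild yields feeding subgroups (FFsGs).
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, mutual_info_score

logger = logging.getLogger("guildspace.cluster")

__all__ = [
    "DistanceMatrix",
    "ClusterPartition",
    "GapCurve",
    "ConsensusGuilds",
    "FFG_NAMES",
    "FFSG_NAMES",
    "euclidean_distance_matrix",
    "hierarchical_cluster",
    "kmeans_cluster",
    "pam_cluster",
    "gap_statistic",
    "silhouette_widths",
    "external_validation",
    "build_consensus_guilds",
    "subcluster_guild",
    "assign_clade_guilds",
    "run_guild_pipeline",
]

FFG_NAMES = [
    "ingestion generalist",
    "prehension specialist",
    "durophagous specialist",
    "shearing pulper",
    "heavy oral processor",
]
FFSG_NAMES = ["basal generalist", "tough generalist", "light oral processor"]


@dataclasses.dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        self.matrix = m

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        pos = {t: i for i, t in enumerate(self.ids)}
        idx = [pos[t] for t in ids]
        return DistanceMatrix(list(ids), self.matrix[np.ix_(idx, idx)], self.metric)


@dataclasses.dataclass
class ClusterPartition:
    method: str                     # hierarchical | kmeans | pam
    k: int
    labels: pd.Series               # taxon -> 1..k
    objective: float
    seed: int | None = None

    def __post_init__(self) -> None:
        labs = set(self.labels)
        if labs != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k}, got {sorted(labs)}")


@dataclasses.dataclass
class GapCurve:
    k_values: np.ndarray
    log_wk: np.ndarray
    expected_log_wk: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    B: int
    chosen_k: int


@dataclasses.dataclass
class ConsensusGuilds:
    """Per-taxon FFG/FFsG labels plus the inconsistent-taxon flag."""

    table: pd.DataFrame             # columns: taxon_id, ffg, ffsg, consistent

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    @property
    def inconsistent(self) -> list[str]:
        return list(self.table.loc[~self.table["consistent"], "taxon_id"])

    def labels(self, resolution: str = "FFG") -> pd.Series:
        """Guild label per taxon; FFsG resolution falls back to the FFG
        for taxa outside any sub-clustered guild."""
        t = self.table.set_index("taxon_id")
        if resolution.upper() == "FFG":
            return t["ffg"]
        if resolution.upper() == "FFSG":
            out = t["ffsg"].where(t["ffsg"] != "", t["ffg"])
            return out
        raise ValueError(f"unknown resolution {resolution!r}")


def euclidean_distance_matrix(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances among the SFMD rows."""
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("matrix contains missing cells")
    return DistanceMatrix(list(matrix.index), squareform(pdist(x)), "euclidean")


# ---------------------------------------------------------------------------
# The three clustering methods
# ---------------------------------------------------------------------------

def _check_k(k: int, n: int) -> None:
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range 2..{n}")


def hierarchical_cluster(d: DistanceMatrix, k: int,
                         linkage: str = "ward") -> ClusterPartition:
    """Agglomerative clustering of the distance matrix cut at k groups."""
    n = len(d.ids)
    _check_k(k, n)
    z = sch.linkage(squareform(d.matrix, checks=False), method=linkage)
    raw = sch.fcluster(z, t=k, criterion="maxclust")
    labels = _canonical_labels(raw)
    height = float(z[n - k - 1, 2]) if k < n else 0.0
    return ClusterPartition("hierarchical", k, pd.Series(labels, index=d.ids), height)


def kmeans_cluster(matrix: pd.DataFrame, k: int, seed: int = 0,
                   n_starts: int = 10) -> ClusterPartition:
    """Best-of-``n_starts`` Lloyd K-means on the SFMD rows."""
    x = matrix.to_numpy(dtype=float)
    _check_k(k, len(x)) if k != 1 else None
    if k == 1:
        labels = np.ones(len(x), dtype=int)
        obj = float(((x - x.mean(axis=0)) ** 2).sum())
        return ClusterPartition("kmeans", 1, pd.Series(labels, index=matrix.index),
                                obj, seed)
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed).fit(x)
    labels = _canonical_labels(km.labels_ + 1)
    return ClusterPartition("kmeans", k, pd.Series(labels, index=matrix.index),
                            float(km.inertia_), seed)


def pam_cluster(d: DistanceMatrix, k: int, seed: int = 0) -> ClusterPartition:
    """Partitioning around medoids: greedy BUILD then steepest-descent SWAP.

    Deterministic for a given matrix; ``seed`` is recorded for the audit
    trail only.
    """
    m = d.matrix
    n = len(m)
    _check_k(k, n)
    medoids = _pam_build(m, k)
    medoids, cost = _pam_swap(m, medoids)
    assign = np.argmin(m[:, medoids], axis=1)
    labels = _canonical_labels(assign + 1)
    part = ClusterPartition("pam", k, pd.Series(labels, index=d.ids),
                            float(cost), seed)
    part.medoids = [d.ids[i] for i in medoids]  # type: ignore[attr-defined]
    return part


def _pam_build(m: np.ndarray, k: int) -> np.ndarray:
    n = len(m)
    medoids = [int(np.argmin(m.sum(axis=0)))]
    while len(medoids) < k:
        nearest = m[:, medoids].min(axis=1)
        # gain of adding candidate j: sum of reductions in nearest distance
        gains = np.maximum(nearest[None, :] - m, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return np.asarray(sorted(medoids))


def _pam_swap(m: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    n = len(m)
    medoids = list(medoids)
    def total(meds):
        return m[:, meds].min(axis=1).sum()
    cost = total(medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        others = [j for j in range(n) if j not in medoids]
        for mi, med in enumerate(medoids):
            rest = medoids[:mi] + medoids[mi + 1:]
            base = m[:, rest].min(axis=1) if rest else np.full(n, np.inf)
            for j in others:
                new_cost = np.minimum(base, m[:, j]).sum()
                delta = cost - new_cost
                if delta > best[0] + 1e-12:
                    best = (delta, mi, j)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            cost = total(medoids)
            improved = True
    return np.asarray(sorted(medoids)), float(cost)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (determinism)."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# Model selection and validation
# ---------------------------------------------------------------------------

def _fit_labels(x: pd.DataFrame, method: str, k: int, seed: int,
                n_starts: int = 3) -> np.ndarray:
    if method == "hierarchical":
        return hierarchical_cluster(euclidean_distance_matrix(x), k).labels.values
    if method == "kmeans":
        return kmeans_cluster(x, k, seed=seed, n_starts=n_starts).labels.values
    if method == "pam":
        return pam_cluster(euclidean_distance_matrix(x), k, seed=seed).labels.values
    raise ValueError(f"unknown method {method!r}")


def _within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    """W_k: summed within-cluster sum of squared deviations from centroids."""
    w = 0.0
    for lab in np.unique(labels):
        sub = x[labels == lab]
        w += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return w


def gap_statistic(
    matrix: pd.DataFrame,
    method: str = "kmeans",
    k_range: tuple[int, int] = (4, 10),
    B: int = 2000,
    seed: int = 0,
) -> GapCurve:
    """Gap statistic over ``k_range`` with B uniform reference data sets.

    References are drawn uniformly inside the bounding box of the data
    after rotation to its principal axes.  Gap(k) = E*[log W_k] − log W_k
    with standard error s_k = sd·sqrt(1 + 1/B); the chosen k is the
    smallest with Gap(k) ≥ Gap(k+1) − s_{k+1} (1-SE rule), falling back
    to the argmax when the rule never fires.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    x = matrix.to_numpy(dtype=float)
    n = len(x)
    ks = np.arange(k_range[0], k_range[1] + 1)
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k range {k_range} outside 2..{n - 1}")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate data: all points identical")
    rng = np.random.default_rng(seed)
    mean = x.mean(axis=0)
    xc = x - mean
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    xp = xc @ vt.T
    lo, hi = xp.min(axis=0), xp.max(axis=0)

    log_wk = np.empty(len(ks))
    for i, k in enumerate(ks):
        labels = _fit_labels(matrix, method, int(k), seed=int(rng.integers(2**31)))
        log_wk[i] = np.log(_within_dispersion(x, labels))

    ref_log = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=xp.shape) @ vt + mean
        ref_df = pd.DataFrame(ref)
        for i, k in enumerate(ks):
            labels = _fit_labels(ref_df, method, int(k),
                                 seed=int(rng.integers(2**31)))
            ref_log[b, i] = np.log(_within_dispersion(ref, labels))

    expected = ref_log.mean(axis=0)
    gap = expected - log_wk
    se = ref_log.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    se = np.maximum(se, 1e-12)
    chosen = None
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            chosen = int(ks[i])
            break
    if chosen is None:
        chosen = int(ks[np.argmax(gap)])
    return GapCurve(ks, log_wk, expected, gap, se, B, chosen)


def silhouette_widths(
    d: DistanceMatrix, p: ClusterPartition
) -> tuple[pd.Series, pd.Series, float]:
    """Silhouette widths s(i) plus per-cluster and overall means.

    s(i) = (b−a)/max(a,b); singleton clusters score 0 by convention.
    """
    labels = p.labels.loc[d.ids].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least two clusters")
    m = d.matrix
    n = len(m)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            s[i] = 0.0
            continue
        a = m[i, own].sum() / (own.sum() - 1)
        b = min(m[i, labels == lab].mean()
                for lab in np.unique(labels) if lab != labels[i])
        s[i] = (b - a) / max(a, b)
    per_point = pd.Series(s, index=d.ids)
    per_cluster = per_point.groupby(p.labels.loc[d.ids]).mean()
    return per_point, per_cluster, float(per_point.mean())


def external_validation(p: ClusterPartition, taxonomy: pd.Series) -> dict:
    """Adjusted Rand index and variation of information vs a taxonomy.

    VI = H(A) + H(B) − 2·I(A,B) in nats; both labelings must cover the
    same taxa.
    """
    if set(p.labels.index) != set(taxonomy.index):
        raise ValueError("partition and taxonomy cover different taxa")
    a = p.labels.loc[p.labels.index].to_numpy()
    b = taxonomy.loc[p.labels.index].to_numpy()
    ari = float(adjusted_rand_score(b, a))
    h_a = _entropy(a)
    h_b = _entropy(b)
    mi = float(mutual_info_score(a, b))
    return {"adjusted_rand": ari, "vi": max(h_a + h_b - 2.0 * mi, 0.0)}


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# Consensus guilds
# ---------------------------------------------------------------------------

def _match_labels(reference: np.ndarray, other: np.ndarray,
                  exact: bool = False) -> np.ndarray:
    """Relabel ``other`` so its clusters align with ``reference``.

    Greedy maximum-overlap on the contingency table by default; the
    Hungarian assignment (``exact=True``) maximises total overlap.
    Unmatched clusters keep fresh labels beyond the reference's range.
    """
    ref_labs = np.unique(reference)
    oth_labs = np.unique(other)
    table = np.zeros((len(ref_labs), len(oth_labs)), dtype=int)
    for i, r in enumerate(ref_labs):
        for j, o in enumerate(oth_labs):
            table[i, j] = int(np.sum((reference == r) & (other == o)))
    mapping: dict[int, int] = {}
    if exact:
        ri, oj = linear_sum_assignment(-table)
        for i, j in zip(ri, oj):
            mapping[oth_labs[j]] = ref_labs[i]
    else:
        t = table.copy()
        while t.max() > -1 and len(mapping) < min(len(ref_labs), len(oth_labs)):
            i, j = np.unravel_index(np.argmax(t), t.shape)
            if t[i, j] < 0:
                break
            mapping[oth_labs[j]] = ref_labs[i]
            t[i, :] = -1
            t[:, j] = -1
    nxt = ref_labs.max() + 1
    for o in oth_labs:
        if o not in mapping:
            mapping[o] = nxt
            nxt += 1
    return np.asarray([mapping[o] for o in other])


def build_consensus_guilds(
    partitions: list[ClusterPartition],
    matrix: pd.DataFrame,
    names: list[str] | None = None,
    exact_matching: bool = False,
) -> ConsensusGuilds:
    """Consensus feeding guilds from the three method partitions.

    Cluster labels of the non-reference methods are matched to the first
    partition by maximum contingency overlap; taxa on which all methods
    then agree are the core guilds, the rest are flagged inconsistent and
    attached (for reporting) to the guild of their nearest core taxon in
    SFMD space.  Guild names are assigned to core clusters in decreasing
    size order.
    """
    if len(partitions) < 3:
        raise ValueError("consensus needs three partitions")
    taxa = list(partitions[0].labels.index)
    for p in partitions[1:]:
        if set(p.labels.index) != set(taxa):
            raise ValueError("partitions cover different taxa")
    ref = partitions[0].labels.loc[taxa].to_numpy()
    matched = [ref]
    for p in partitions[1:]:
        matched.append(_match_labels(ref, p.labels.loc[taxa].to_numpy(),
                                     exact=exact_matching))
    matched = np.vstack(matched)
    consistent = np.all(matched == matched[0], axis=0)
    if not consistent.any():
        raise ValueError("no taxon is consistently classified")
    core_labels = matched[0]

    counts = Counter(core_labels[consistent])
    ordered = [lab for lab, _ in counts.most_common()]
    if names is None:
        names = FFG_NAMES
    name_of = {lab: (names[i] if i < len(names) else f"FFG_{i + 1}")
               for i, lab in enumerate(ordered)}

    x = matrix.loc[taxa].to_numpy(dtype=float)
    ffg = []
    for i, t in enumerate(taxa):
        if consistent[i]:
            ffg.append(name_of[core_labels[i]])
        else:
            core_idx = np.flatnonzero(consistent)
            dists = np.linalg.norm(x[core_idx] - x[i], axis=1)
            nearest = core_idx[int(np.argmin(dists))]
            ffg.append(name_of[core_labels[nearest]])
    n_inc = int((~consistent).sum())
    if n_inc:
        logger.info("%d taxa inconsistent across methods; attached to nearest "
                    "core guild", n_inc)
    table = pd.DataFrame({
        "taxon_id": taxa,
        "ffg": ffg,
        "ffsg": [""] * len(taxa),
        "consistent": consistent,
    })
    return ConsensusGuilds(table)


def run_guild_pipeline(
    matrix: pd.DataFrame,
    k_range: tuple[int, int] = (4, 10),
    B: int = 2000,
    seed: int = 0,
    names: list[str] | None = None,
    k_override: int | None = None,
) -> tuple[ConsensusGuilds, dict[str, GapCurve], list[ClusterPartition]]:
    """Distance → gap-selected k → three partitions → consensus guilds.

    The gap statistic is run per method; the consensus k is the modal
    choice (ties broken toward fewer clusters).  ``k_override`` skips
    model selection.
    """
    d = euclidean_distance_matrix(matrix)
    rng = np.random.default_rng(seed)
    gaps: dict[str, GapCurve] = {}
    if k_override is None:
        for method in ("hierarchical", "kmeans", "pam"):
            gaps[method] = gap_statistic(matrix, method, k_range, B,
                                         seed=int(rng.integers(2**31)))
        votes = Counter(g.chosen_k for g in gaps.values())
        top = max(votes.values())
        k = min(kk for kk, v in votes.items() if v == top)
    else:
        k = k_override
    parts = [
        hierarchical_cluster(d, k),
        kmeans_cluster(matrix, k, seed=int(rng.integers(2**31))),
        pam_cluster(d, k, seed=int(rng.integers(2**31))),
    ]
    guilds = build_consensus_guilds(parts, matrix, names=names)
    return guilds, gaps, parts


def subcluster_guild(
    guilds: ConsensusGuilds,
    guild: str,
    matrix: pd.DataFrame,
    k_range: tuple[int, int] = (2, 6),
    B: int = 100,
    seed: int = 0,
    names: list[str] | None = None,
) -> ConsensusGuilds:
    """Re-run the full consensus pipeline inside one guild (FFsG labels).

    Only that guild's taxa receive ``ffsg`` labels; everyone else keeps
    an empty entry.
    """
    members = list(guilds.table.loc[guilds.table["ffg"] == guild, "taxon_id"])
    if len(members) <= k_range[1]:
        raise ValueError(
            f"guild {guild!r} has {len(members)} members; needs > {k_range[1]}"
        )
    sub = matrix.loc[members]
    sub_guilds, _, _ = run_guild_pipeline(
        sub, k_range=k_range, B=B, seed=seed,
        names=names if names is not None else FFSG_NAMES,
    )
    table = guilds.table.copy()
    ffsg_map = sub_guilds.table.set_index("taxon_id")["ffg"]
    mask = table["taxon_id"].isin(members)
    table.loc[mask, "ffsg"] = table.loc[mask, "taxon_id"].map(ffsg_map)
    return ConsensusGuilds(table)


def assign_clade_guilds(guilds: ConsensusGuilds, taxonomy: pd.Series) -> dict:
    """Clade → FFG by plurality of the clade's consistent taxa.

    Ties and clades with no consistent taxa come back as "unresolved".
    """
    t = guilds.table.set_index("taxon_id")
    missing = [x for x in t.index if x not in taxonomy.index]
    if missing:
        raise ValueError(f"taxa without a clade: {missing}")
    out: dict[str, str] = {}
    for clade, members in taxonomy.groupby(taxonomy):
        sub = t.loc[t.index.intersection(members.index)]
        sub = sub.loc[sub["consistent"]]
        if sub.empty:
            out[str(clade)] = "unresolved"
            continue
        counts = sub["ffg"].value_counts()
        top = counts[counts == counts.max()]
        out[str(clade)] = top.index[0] if len(top) == 1 else "unresolved"
    return out
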