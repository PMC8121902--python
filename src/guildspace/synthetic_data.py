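"""Synthetic study-scale inputs with known (planted) structure.

Every stage of the pipeline can be exercised without downloads: jaw
outlines deformed from a common 59-landmark template (4 fixed points, 55
sliding semilandmarks on 4 curves), an 8-character functional table with
guild clusters planted at a controlled separation, clade labels with a
configurable guild fidelity, stratigraphic ranges over the
Changhsingian–Toarcian scheme, and locality assemblages with abundance
counts.  The generator is deliberately independent of the analysis code:
deformations are low-order trigonometric displacement fields, not
thin-plate splines, and guild structure is planted directly in character
space.

Defaults mirror the study scale: 136 taxa, 5 guilds, 8 characters, 59
landmarks, separation 6 within-guild standard deviations.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .functional_characters import CHARACTERS, MEASUREMENTS
from .io_formats import LandmarkConfiguration, TimeBinScheme, default_timebins

logger = logging.getLogger("guildspace.synth")

__all__ = [
    "SyntheticConfig",
    "generate_functional_table",
    "generate_shape_set",
    "generate_ranges_and_assemblages",
    "TEMPLATE_FIXED",
    "TEMPLATE_CURVES",
    "jaw_template",
]

# 59-point outline scheme: fixed anchors at the start of each of 4 curves
TEMPLATE_FIXED = [0, 14, 29, 43]
TEMPLATE_CURVES = [
    list(range(1, 14)),
    list(range(15, 29)),
    list(range(30, 43)),
    list(range(44, 59)),
]

# plausible raw scales for the eight characters (mean, SD across taxa)
_CHAR_SCALE = {
    "MA_ant": (0.28, 0.05),
    "MA_post": (0.60, 0.10),
    "MA_open": (0.22, 0.04),
    "MAR": (0.26, 0.05),
    "RSL": (0.22, 0.04),
    "AO": (0.075, 0.018),
    "RTL": (0.55, 0.08),
    "SA": (35.0, 8.0),
}


@dataclasses.dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the study-scale conditions."""

    n_taxa: int = 136
    n_guilds: int = 5
    separation: float = 6.0       # min centre distance, within-guild SD units
    within_sd: float = 1.0
    n_clades: int = 10
    fidelity: float = 0.9         # P(clade member falls in clade's home guild)
    n_subguilds: int = 1          # planted subclusters inside guild 1
    sub_separation: float = 0.0   # their centre separation, within-SD units
    n_shape_groups: int = 2
    deformation: float = 0.05     # low-frequency field amplitude (shape units)
    noise: float = 0.005          # iid landmark noise SD
    apply_similarity: bool = True
    mean_extra_bins: float = 2.0  # geometric range-length beyond the FAD bin
    n_faunivores: int = 40
    n_assemblages: int = 12
    mean_assemblage_size: float = 8.0
    planted_conflict_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 0.0 <= self.fidelity <= 1.0:
            raise ValueError("fidelity must be in [0, 1]")
        for f in ("n_taxa", "n_guilds", "n_clades", "n_assemblages"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def _guild_centres(rng: np.random.Generator, n_guilds: int, dim: int,
                   separation: float, within_sd: float) -> np.ndarray:
    """Centres in z-space whose minimum pairwise distance is the stated
    separation (in within-guild SD units)."""
    if separation == 0.0 or n_guilds == 1:
        return np.zeros((n_guilds, dim))
    c = rng.normal(size=(n_guilds, dim))
    dmin = min(np.linalg.norm(c[i] - c[j])
               for i in range(n_guilds) for j in range(i + 1, n_guilds))
    return c * (separation * within_sd / dmin)


def generate_functional_table(
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    as_measurements: bool = False,
    return_subguilds: bool = False,
) -> tuple:
    """Planted-guild functional data: ``(table, guild_truth, clades)``.

    Members are Gaussian about their guild centre at the configured
    within-guild SD; each clade has a home guild that its members join
    with probability ``fidelity`` (else uniform).  With ``n_subguilds``
    > 1 and a positive ``sub_separation``, guild 1's members get
    additional sub-centre offsets (returned as a fourth series when
    ``return_subguilds`` is set).  With ``as_measurements`` the
    characters are back-solved into a consistent positive-length
    measurement table so the ratio stage can be exercised end to end
    (infeasible draws are resampled, logged).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    centres = _guild_centres(rng, cfg.n_guilds, len(CHARACTERS),
                             cfg.separation, cfg.within_sd)
    taxa = [f"taxon_{i:03d}" for i in range(cfg.n_taxa)]
    clade_of = np.array([i % cfg.n_clades for i in range(cfg.n_taxa)])
    home = np.array([c % cfg.n_guilds for c in range(cfg.n_clades)])
    guild = np.where(
        rng.uniform(size=cfg.n_taxa) < cfg.fidelity,
        home[clade_of],
        rng.integers(0, cfg.n_guilds, size=cfg.n_taxa),
    )
    z = centres[guild] + rng.normal(scale=cfg.within_sd,
                                    size=(cfg.n_taxa, len(CHARACTERS)))
    sub_label = np.array([""] * cfg.n_taxa, dtype=object)
    if cfg.n_subguilds > 1 and cfg.sub_separation > 0.0:
        sub_centres = _guild_centres(rng, cfg.n_subguilds, len(CHARACTERS),
                                     cfg.sub_separation, cfg.within_sd)
        members = np.flatnonzero(guild == 0)
        sub = rng.integers(0, cfg.n_subguilds, size=len(members))
        z[members] += sub_centres[sub]
        sub_label[members] = [f"sub_{s + 1}" for s in sub]
    scale = np.array([_CHAR_SCALE[c] for c in CHARACTERS])
    raw = scale[:, 0] + z * scale[:, 1]
    if as_measurements:
        raw = _make_feasible(raw, centres, guild, scale, cfg, rng)
    table = pd.DataFrame(raw, index=pd.Index(taxa, name="taxon_id"),
                         columns=CHARACTERS)
    truth = pd.Series([f"guild_{g + 1}" for g in guild], index=table.index,
                      name="true_guild")
    clades = pd.Series([f"clade_{c + 1}" for c in clade_of], index=table.index,
                       name="clade")
    if as_measurements:
        table = _back_solve(table, rng)
    if return_subguilds:
        subs = pd.Series(sub_label, index=table.index if not as_measurements
                         else pd.Index(taxa, name="taxon_id"),
                         name="true_subguild")
        return table, truth, clades, subs
    return table, truth, clades


def _feasible(row: np.ndarray) -> bool:
    chars = dict(zip(CHARACTERS, row))
    if any(chars[c] <= 0 for c in CHARACTERS if c != "SA"):
        return False
    if not 0 <= chars["SA"] < 180:
        return False
    # posterior bite point lies behind the anterior one
    return chars["MA_post"] >= chars["MA_ant"]


def _make_feasible(raw, centres, guild, scale, cfg, rng, max_tries=200):
    out = raw.copy()
    n_resampled = 0
    for i in range(len(out)):
        tries = 0
        while not _feasible(out[i]) and tries < max_tries:
            z = centres[guild[i]] + rng.normal(scale=cfg.within_sd,
                                               size=len(CHARACTERS))
            out[i] = scale[:, 0] + z * scale[:, 1]
            tries += 1
        if tries:
            n_resampled += 1
        if not _feasible(out[i]):
            raise ValueError(
                f"could not back-solve a feasible measurement row "
                f"(taxon index {i}); lower separation or within_sd"
            )
    if n_resampled:
        logger.info("resampled %d infeasible character row(s)", n_resampled)
    return out


def _back_solve(table: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Invert the ratio definitions into positive raw lengths (mm)."""
    n = len(table)
    jaw = 80.0 * np.exp(rng.normal(scale=0.3, size=n))      # jaw lengths, mm
    out = pd.DataFrame(index=table.index)
    out["jaw_length"] = jaw
    out["outlever_anterior"] = 0.9 * jaw
    out["inlever_closing"] = table["MA_ant"] * out["outlever_anterior"]
    out["outlever_posterior"] = out["inlever_closing"] / table["MA_post"]
    out["inlever_opening"] = table["MA_open"] * out["outlever_anterior"]
    out["max_depth"] = table["MAR"] * jaw
    out["symphysis_length"] = table["RSL"] * jaw
    out["articulation_offset_raw"] = table["AO"] * jaw
    out["tooth_row_length"] = table["RTL"] * jaw
    out["symphysis_angle"] = table["SA"]
    return out.reset_index()[["taxon_id"] + MEASUREMENTS]


# ---------------------------------------------------------------------------
# Shapes
# ---------------------------------------------------------------------------

def jaw_template() -> np.ndarray:
    """Elongate mandible-like outline: 59 points on a 4:1 ellipse with a
    raised posterior (coronoid) region."""
    t = 2.0 * np.pi * np.arange(59) / 59.0
    r = 1.0 + 0.15 * np.cos(2 * t + 0.7)
    x = r * np.cos(t)
    y = 0.25 * r * np.sin(t)
    return np.column_stack([x, y])


def generate_shape_set(
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    n_shapes: int | None = None,
) -> tuple[list[LandmarkConfiguration], pd.Series]:
    """Deformed template outlines: ``(configurations, group_truth)``.

    Each group gets its own smooth low-frequency radial displacement
    field of the configured magnitude; iid landmark noise and a random
    similarity transform (rotation, scale, translation) are layered on
    top so superimposition has work to do.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_taxa if n_shapes is None else n_shapes
    base = jaw_template()
    t = 2.0 * np.pi * np.arange(len(base)) / len(base)
    groups = np.arange(n) % cfg.n_shape_groups
    # per-group deformation field coefficients, harmonics 2..4
    coef = rng.normal(scale=cfg.deformation,
                      size=(cfg.n_shape_groups, 3, 2))
    shapes = []
    for i in range(n):
        g = groups[i]
        disp = np.zeros(len(base))
        for h, k in enumerate(range(2, 5)):
            disp += coef[g, h, 0] * np.cos(k * t) + coef[g, h, 1] * np.sin(k * t)
        radial = base / np.maximum(np.linalg.norm(base, axis=1), 1e-9)[:, None]
        pts = base + disp[:, None] * radial
        pts = pts + rng.normal(scale=cfg.noise, size=pts.shape)
        if cfg.apply_similarity:
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            s = np.exp(rng.normal(scale=0.4))
            shift = rng.normal(scale=3.0, size=2)
            pts = s * pts @ rot.T + shift
        shapes.append(LandmarkConfiguration(
            f"taxon_{i:03d}", pts, list(TEMPLATE_FIXED),
            [list(c) for c in TEMPLATE_CURVES],
        ))
    truth = pd.Series([f"group_{g + 1}" for g in groups],
                      index=[s.specimen_id for s in shapes], name="true_group")
    return shapes, truth


# ---------------------------------------------------------------------------
# Ranges and assemblages
# ---------------------------------------------------------------------------

def generate_ranges_and_assemblages(
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    guilds: pd.Series | None = None,
    clades: pd.Series | None = None,
    bins: TimeBinScheme | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratigraphic ranges and locality assemblages.

    Returns ``(taxa_table, assemblage_table)`` in the io_formats CSV
    schemas.  First-appearance bins are uniform over the scheme, range
    lengths geometric with the configured mean; assemblages draw
    co-occurring taxa from one bin with log-normal abundance counts.
    With ``planted_conflict_pairs`` > 0 and guild labels supplied, that
    many disjoint same-guild herbivore pairs are forced into the first
    locality.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    bins = default_timebins() if bins is None else bins
    names = bins.names
    herb = [f"taxon_{i:03d}" for i in range(cfg.n_taxa)]
    faun = [f"faunivore_{i:03d}" for i in range(cfg.n_faunivores)]
    if clades is None:
        clades = pd.Series({t: f"clade_{(i % cfg.n_clades) + 1}"
                            for i, t in enumerate(herb)})
    rows = []
    for i, t in enumerate(herb + faun):
        fad = int(rng.integers(0, len(names)))
        if cfg.mean_extra_bins <= 0:
            extra = 0
        else:
            extra = int(rng.geometric(1.0 / (1.0 + cfg.mean_extra_bins)) - 1)
        lad = min(fad + extra, len(names) - 1)
        is_herb = i < len(herb)
        rows.append({
            "taxon_id": t,
            "clade": clades.get(t, "Faunivora"),
            "subclade": clades.get(t, "Faunivora") + "_sub",
            "first_bin": names[fad],
            "last_bin": names[lad],
            "diet": "herbivore" if is_herb else "faunivore",
        })
    taxa = pd.DataFrame(rows)

    by_bin: dict[str, list[str]] = {b: [] for b in names}
    for r in rows:
        for b in bins.span(r["first_bin"], r["last_bin"]):
            by_bin[b].append(r["taxon_id"])
    occupied = [b for b in names if len(by_bin[b]) >= 2]
    arows = []
    for a in range(cfg.n_assemblages):
        b = occupied[int(rng.integers(0, len(occupied)))]
        pool = by_bin[b]
        size = min(len(pool), max(2, int(rng.poisson(cfg.mean_assemblage_size))))
        members = list(rng.choice(pool, size=size, replace=False))
        if a == 0 and cfg.planted_conflict_pairs > 0 and guilds is not None:
            members = _plant_conflicts(members, guilds,
                                       cfg.planted_conflict_pairs)
        for t in members:
            count = max(1, int(round(np.exp(rng.normal(1.5, 0.8)))))
            arows.append({"locality": f"loc_{a:02d}", "bin": b,
                          "taxon_id": t, "count": count})
    return taxa, pd.DataFrame(arows)


def _plant_conflicts(members: list[str], guilds: pd.Series,
                     n_pairs: int) -> list[str]:
    """Force exactly ``n_pairs`` disjoint same-guild pairs into the
    member list, one pair per guild, removing other conflicts."""
    by_guild: dict[str, list[str]] = {}
    for t in guilds.index:
        by_guild.setdefault(str(guilds[t]), []).append(t)
    eligible = [g for g, ts in sorted(by_guild.items()) if len(ts) >= 2]
    if len(eligible) < n_pairs:
        raise ValueError(f"cannot plant {n_pairs} pairs: only "
                         f"{len(eligible)} guilds have >= 2 taxa")
    out: list[str] = []
    used_guilds = eligible[:n_pairs]
    for g in used_guilds:
        out.extend(by_guild[g][:2])
    # pad with at most one taxon per remaining guild (no extra conflicts)
    for g in eligible[n_pairs:]:
        if len(out) >= len(members):
            break
        out.append(by_guild[g][0])
    return out
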