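"""The eight biomechanical jaw characters and their z-standardisation.

Seven dimensionless ratios plus the symphyseal angle summarise mandibular
lever mechanics and robusticity:

===========  ==========================================================
MA_ant       closing in-lever / anterior out-lever (bite force, front)
MA_post      closing in-lever / posterior out-lever (bite force, back)
MA_open      opening in-lever / anterior out-lever (opening speed)
MAR          maximum mandible depth / jaw length (robusticity)
RSL          symphysis length / jaw length
AO           perpendicular joint offset from tooth row / jaw length
RTL          tooth-row (or functional-surface) length / jaw length
SA           symphyseal angle, degrees (passed through)
===========  ==========================================================

All ratios are invariant to the measurement unit; for edentulous taxa the
tooth-row measurement is the length of the mandibular functional surface.
The standardised table (SFMD) is the column-wise z-score with sample
(n-1) standard deviations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("guildspace.functional")

__all__ = [
    "CHARACTERS",
    "MEASUREMENTS",
    "compute_functional_characters",
    "z_standardize",
]

CHARACTERS = ["MA_ant", "MA_post", "MA_open", "MAR", "RSL", "AO", "RTL", "SA"]

MEASUREMENTS = [
    "jaw_length",
    "tooth_row_length",
    "max_depth",
    "symphysis_length",
    "symphysis_angle",
    "inlever_closing",
    "inlever_opening",
    "outlever_anterior",
    "outlever_posterior",
    "articulation_offset_raw",
]

# character -> (numerator measurement, denominator measurement)
_RATIOS = {
    "MA_ant": ("inlever_closing", "outlever_anterior"),
    "MA_post": ("inlever_closing", "outlever_posterior"),
    "MA_open": ("inlever_opening", "outlever_anterior"),
    "MAR": ("max_depth", "jaw_length"),
    "RSL": ("symphysis_length", "jaw_length"),
    "AO": ("articulation_offset_raw", "jaw_length"),
    "RTL": ("tooth_row_length", "jaw_length"),
}


def compute_functional_characters(measurements: pd.DataFrame) -> pd.DataFrame:
    """Derive the 8-character table from raw linear measurements.

    Taxa with any missing measurement are dropped (listwise) with a log
    entry; a zero or negative denominator is a data error naming the taxon
    and character.  Returns a DataFrame indexed by ``taxon_id`` with the
    columns of :data:`CHARACTERS`.
    """
    m = measurements.set_index("taxon_id") if "taxon_id" in measurements.columns \
        else measurements.copy()
    missing_cols = [c for c in MEASUREMENTS if c not in m.columns]
    if missing_cols:
        raise KeyError(f"measurement table missing column(s) {missing_cols}")
    complete = m[MEASUREMENTS].notna().all(axis=1)
    dropped = list(m.index[~complete])
    if dropped:
        logger.info("dropping %d taxa with missing measurements: %s",
                    len(dropped), dropped)
    m = m.loc[complete]
    out = pd.DataFrame(index=m.index)
    for char, (num, den) in _RATIOS.items():
        bad = m.index[m[den] <= 0]
        if len(bad):
            raise ValueError(
                f"non-positive denominator {den!r} for character {char!r} "
                f"in taxa {list(bad)}"
            )
        out[char] = m[num] / m[den]
    sa = m["symphysis_angle"]
    if ((sa < 0) | (sa >= 180)).any():
        bad = list(m.index[(sa < 0) | (sa >= 180)])
        raise ValueError(f"symphyseal angle outside [0, 180) for taxa {bad}")
    out["SA"] = sa
    if (out[[c for c in CHARACTERS if c != "SA"]] <= 0).any().any():
        bad = out.index[(out[[c for c in CHARACTERS if c != "SA"]] <= 0).any(axis=1)]
        raise ValueError(f"non-positive ratio character for taxa {list(bad)}")
    return out[CHARACTERS]


def z_standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-wise z-transform with sample (n-1) SD.

    Returns ``(sfmd, params)`` where ``params`` holds the per-character
    mean and SD used, so the transform can be inverted or re-applied to
    new taxa.  Zero-variance columns are an error naming the character.
    """
    if len(table) < 2:
        raise ValueError("need at least two taxa to standardise")
    means = table.mean(axis=0)
    sds = table.std(axis=0, ddof=1)
    zero = sds.index[sds == 0.0]
    if len(zero):
        raise ValueError(f"zero-variance character(s): {list(zero)}")
    z = (table - means) / sds
    params = pd.DataFrame({"mean": means, "sd": sds})
    return z, params
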