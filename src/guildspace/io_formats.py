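"""Readers and writers for the pipeline's standard inputs and outputs.

Landmark data travel as TPS records, everything tabular as CSV, and the
stage/substage time scale as a small bins table.  The TPS dialect accepted
here covers the keys ``LM=``, ``ID=``, ``SCALE=``, ``CURVES=`` and
``POINTS=`` (case-insensitive).  Coordinates in the ``LM`` block are the
full outline in digitising order.  ``CURVES=c`` followed by ``c``
``POINTS=m`` lines partitions that outline into ``c`` runs of ``m``
sliding semilandmarks, each run anchored by the fixed landmark that
precedes it (the outline starts at a fixed landmark and fixed landmarks
are interleaved between runs).  When ``CURVES`` is absent the sliding
structure must come from a sidecar slider CSV with columns
``semilandmark,left,right`` (0-based indices).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("guildspace.io")

__all__ = [
    "LandmarkConfiguration",
    "TaxonRecord",
    "TimeBinScheme",
    "TpsFormatError",
    "SchemaError",
    "read_tps",
    "write_tps",
    "read_sliders",
    "read_table",
    "write_results",
    "read_results",
    "default_timebins",
    "load_config",
]


class TpsFormatError(ValueError):
    """Malformed TPS record (bad count, non-numeric coordinate, ...)."""


class SchemaError(ValueError):
    """CSV table does not conform to the requested schema."""


@dataclasses.dataclass
class LandmarkConfiguration:
    """One specimen's 2D landmarks: fixed points plus semilandmark curves.

    ``coords`` holds every point (fixed and sliding) in outline order,
    already multiplied by ``scale`` when a SCALE key was present.
    ``curves`` lists the semilandmark indices of each curve; each curve is
    a consecutive run anchored on both sides by fixed (or terminal)
    points.
    """

    specimen_id: str
    coords: np.ndarray                     # (n, 2)
    fixed_indices: list[int]
    curves: list[list[int]]
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        n = len(self.coords)
        semis = [i for c in self.curves for i in c]
        all_idx = list(self.fixed_indices) + semis
        if len(set(all_idx)) != len(all_idx):
            raise ValueError("landmark indices must be unique")
        if all_idx and (min(all_idx) < 0 or max(all_idx) >= n):
            raise ValueError("landmark index out of range")
        if len(all_idx) != n:
            raise ValueError(
                f"{self.specimen_id}: fixed + semilandmarks ({len(all_idx)}) "
                f"!= total landmarks ({n})"
            )
        for c in self.curves:
            if any(b - a != 1 for a, b in zip(c, c[1:])):
                raise ValueError("curve semilandmarks must be consecutive")

    @property
    def n_landmarks(self) -> int:
        return len(self.coords)

    def slider_table(self) -> np.ndarray:
        """(semilandmark, left, right) neighbour triples for sliding.

        Neighbours are the immediately adjacent outline points, fixed or
        sliding; anchors themselves never slide.
        """
        rows = []
        for curve in self.curves:
            for i in curve:
                rows.append((i, i - 1, (i + 1) % self.n_landmarks))
        return np.asarray(rows, dtype=int)


@dataclasses.dataclass
class TaxonRecord:
    taxon_id: str
    clade: str
    subclade: str
    first_bin: str
    last_bin: str
    diet: str  # "herbivore" | "faunivore"


class TimeBinScheme:
    """Ordered geological time bins with absolute ages in Ma.

    Bins are stored oldest first; ``start`` is the older bound so
    ``start > end`` for every bin and consecutive bins share a boundary.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"bin", "start", "end"}
        if not required.issubset(table.columns):
            raise SchemaError(f"bins table needs columns {sorted(required)}")
        t = table.reset_index(drop=True).copy()
        if (t["start"] <= t["end"]).any():
            raise ValueError("each bin must have start (older) > end in Ma")
        diffs = t["start"].values[1:] - t["end"].values[:-1]
        if not np.allclose(diffs, 0.0):
            raise ValueError("bins must be contiguous and ordered old to young")
        t["midpoint"] = (t["start"] + t["end"]) / 2.0
        self.table = t
        self._order = {b: i for i, b in enumerate(t["bin"])}

    @property
    def names(self) -> list[str]:
        return list(self.table["bin"])

    def index(self, name: str) -> int:
        try:
            return self._order[name]
        except KeyError:
            raise KeyError(f"unknown time bin: {name!r}") from None

    def span(self, first: str, last: str) -> list[str]:
        i, j = self.index(first), self.index(last)
        if i > j:
            raise ValueError(f"first_bin {first!r} is younger than last_bin {last!r}")
        return self.names[i : j + 1]

    def epoch_of(self, name: str) -> str:
        self.index(name)
        if "epoch" in self.table.columns:
            return str(self.table.set_index("bin").loc[name, "epoch"])
        raise KeyError("scheme has no epoch column")


# Stage/substage scale, Changhsingian -> Toarcian, ages from the 2019 ICS chart;
# Carnian and Norian split into sub-bins as used throughout the pipeline.
_DEFAULT_BINS = [
    ("Changhsingian", 254.14, 251.902, "Lopingian"),
    ("Induan", 251.902, 251.2, "Early Triassic"),
    ("Olenekian", 251.2, 247.2, "Early Triassic"),
    ("Anisian", 247.2, 242.0, "Middle Triassic"),
    ("Ladinian", 242.0, 237.0, "Middle Triassic"),
    ("lower Carnian", 237.0, 233.0, "Late Triassic"),
    ("upper Carnian", 233.0, 227.0, "Late Triassic"),
    ("lower Norian", 227.0, 221.0, "Late Triassic"),
    ("middle Norian", 221.0, 214.5, "Late Triassic"),
    ("upper Norian", 214.5, 208.5, "Late Triassic"),
    ("Rhaetian", 208.5, 201.3, "Late Triassic"),
    ("Hettangian", 201.3, 199.3, "Early Jurassic"),
    ("Sinemurian", 199.3, 190.8, "Early Jurassic"),
    ("Pliensbachian", 190.8, 182.7, "Early Jurassic"),
    ("Toarcian", 182.7, 174.1, "Early Jurassic"),
]


def default_timebins() -> TimeBinScheme:
    """The default Changhsingian–Toarcian stage/substage scheme."""
    df = pd.DataFrame(_DEFAULT_BINS, columns=["bin", "start", "end", "epoch"])
    return TimeBinScheme(df)


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

def _parse_point(line: str, lineno: int) -> tuple[float, float]:
    parts = line.split()
    if len(parts) != 2:
        raise TpsFormatError(f"line {lineno}: expected 'x y', got {line!r}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError:
        raise TpsFormatError(
            f"line {lineno}: non-numeric coordinate in {line!r}"
        ) from None


def read_tps(
    path: str | Path,
    sliders: np.ndarray | None = None,
) -> list[LandmarkConfiguration]:
    """Parse a TPS file into one :class:`LandmarkConfiguration` per record.

    ``sliders`` is the sidecar (semilandmark, left, right) table used when
    records carry no CURVES blocks; it must then cover every record.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    records: list[LandmarkConfiguration] = []
    i = 0
    rec_no = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        key = line.upper()
        if not key.startswith("LM="):
            raise TpsFormatError(f"line {i + 1}: expected LM= header, got {line!r}")
        rec_no += 1
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError:
            raise TpsFormatError(f"line {i + 1}: bad LM count in {line!r}") from None
        i += 1
        coords = []
        while i < n_lines and len(coords) < n_lm:
            s = lines[i].strip()
            if not s or "=" in s:
                break
            coords.append(_parse_point(s, i + 1))
            i += 1
        if len(coords) != n_lm:
            raise TpsFormatError(
                f"record {rec_no}: LM={n_lm} but found {len(coords)} coordinate lines"
            )
        curve_sizes: list[int] = []
        specimen_id = f"record_{rec_no}"
        scale: float | None = None
        n_curves_declared: int | None = None
        while i < n_lines:
            s = lines[i].strip()
            if not s:
                i += 1
                continue
            up = s.upper()
            if up.startswith("LM="):
                break
            if up.startswith("CURVES="):
                n_curves_declared = int(s.split("=", 1)[1])
            elif up.startswith("POINTS="):
                curve_sizes.append(int(s.split("=", 1)[1]))
            elif up.startswith("ID="):
                specimen_id = s.split("=", 1)[1].strip()
            elif up.startswith("SCALE="):
                scale = float(s.split("=", 1)[1])
            elif up.startswith("IMAGE=") or up.startswith("COMMENT="):
                pass
            else:
                raise TpsFormatError(f"line {i + 1}: unrecognised key {s!r}")
            i += 1
        if n_curves_declared is not None and n_curves_declared != len(curve_sizes):
            raise TpsFormatError(
                f"record {rec_no} ({specimen_id}): CURVES={n_curves_declared} "
                f"but {len(curve_sizes)} POINTS lines"
            )
        xy = np.asarray(coords, dtype=float)
        if scale is not None:
            xy = xy * scale
        if curve_sizes:
            fixed, curves = _structure_from_curve_sizes(n_lm, curve_sizes, rec_no)
        elif sliders is not None:
            semis = sorted(int(r[0]) for r in np.asarray(sliders))
            fixed = [j for j in range(n_lm) if j not in set(semis)]
            curves = _runs(semis)
        else:
            fixed, curves = list(range(n_lm)), []
        records.append(
            LandmarkConfiguration(specimen_id, xy, fixed, curves, scale)
        )
    if not records:
        raise TpsFormatError(f"{path}: no TPS records found")
    return records


def _structure_from_curve_sizes(
    n_lm: int, sizes: Sequence[int], rec_no: int
) -> tuple[list[int], list[list[int]]]:
    """Interleave fixed anchors with semilandmark runs along the outline."""
    total = len(sizes) + sum(sizes)
    if total != n_lm:
        raise TpsFormatError(
            f"record {rec_no}: {len(sizes)} curves with {sum(sizes)} "
            f"semilandmarks need {total} points, LM={n_lm}"
        )
    fixed, curves, pos = [], [], 0
    for m in sizes:
        fixed.append(pos)
        curves.append(list(range(pos + 1, pos + 1 + m)))
        pos += 1 + m
    return fixed, curves


def _runs(sorted_idx: list[int]) -> list[list[int]]:
    runs: list[list[int]] = []
    for j in sorted_idx:
        if runs and j == runs[-1][-1] + 1:
            runs[-1].append(j)
        else:
            runs.append([j])
    return runs


def write_tps(path: str | Path, shapes: Sequence[LandmarkConfiguration]) -> None:
    """Write configurations in the dialect :func:`read_tps` accepts.

    Coordinates are written post-scale, so no SCALE key is emitted.
    """
    out = []
    for s in shapes:
        out.append(f"LM={s.n_landmarks}")
        out.extend(f"{x:.10g} {y:.10g}" for x, y in s.coords)
        if s.curves:
            out.append(f"CURVES={len(s.curves)}")
            out.extend(f"POINTS={len(c)}" for c in s.curves)
        out.append(f"ID={s.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


def read_sliders(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    need = {"semilandmark", "left", "right"}
    if not need.issubset(df.columns):
        raise SchemaError(f"slider table needs columns {sorted(need)}")
    return df[["semilandmark", "left", "right"]].to_numpy(dtype=int)


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

_SCHEMAS: dict[str, dict] = {
    "measurements": {
        "required": ["taxon_id"],
        "numeric": [
            "jaw_length", "tooth_row_length", "max_depth", "symphysis_length",
            "symphysis_angle", "inlever_closing", "inlever_opening",
            "outlever_anterior", "outlever_posterior", "articulation_offset_raw",
        ],
    },
    "taxa": {
        "required": ["taxon_id", "clade", "subclade", "first_bin", "last_bin", "diet"],
        "numeric": [],
    },
    "assemblages": {
        "required": ["locality", "bin", "taxon_id"],
        "numeric": ["count"],
    },
    "bins": {"required": ["bin", "start", "end"], "numeric": ["start", "end"]},
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate one of the pipeline's CSV inputs.

    Missing numeric cells stay as NaN (flagged, never coerced); duplicate
    taxon ids in the taxa/measurements tables are a validation error.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; one of {sorted(_SCHEMAS)}")
    spec = _SCHEMAS[schema]
    df = pd.read_csv(path)
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for c in spec["numeric"]:
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="raise")
    if schema in ("taxa", "measurements") and df["taxon_id"].duplicated().any():
        dups = df.loc[df["taxon_id"].duplicated(), "taxon_id"].tolist()
        raise SchemaError(f"{path}: duplicate taxon_id values {dups}")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.info("%s: %d missing cell(s) flagged", path, n_missing)
    return df


def check_references(
    table: pd.DataFrame, taxa: pd.DataFrame, bins: TimeBinScheme | None = None
) -> list[str]:
    """Cross-check taxon and bin references; returns warning strings."""
    warnings = []
    known = set(taxa["taxon_id"])
    for t in table.get("taxon_id", pd.Series(dtype=str)):
        if t not in known:
            warnings.append(f"unknown taxon: {t}")
    if bins is not None and "bin" in table.columns:
        for b in table["bin"].unique():
            if b not in bins._order:
                warnings.append(f"unknown bin: {b}")
    for w in warnings:
        logger.warning(w)
    return warnings


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def write_results(obj, path: str | Path) -> None:
    """Write a pipeline product: DataFrames as CSV, mappings as JSON."""
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False, float_format="%.12g")
    elif isinstance(obj, dict):
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    elif hasattr(obj, "to_frame"):
        obj.to_frame().to_csv(path, index=False, float_format="%.12g")
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def read_results(path: str | Path) -> pd.DataFrame | dict:
    path = Path(path)
    if path.suffix == ".json":
        return json.loads(path.read_text())
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    """Load the structured YAML config controlling every stage."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg
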