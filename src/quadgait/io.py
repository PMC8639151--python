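"""Delimited-text readers and writers for the gait-data schemas.

All tables are comma-separated UTF-8 with dot decimals and a one-line
versioned header comment (``# quadgait:<schema>.v1 key=value ...``).
Times are seconds, positions centimeters, angles degrees; frame indices
are 0-based.

Schemas
-------
marker table
    ``animal, pass, frame, time_s, marker, limb, x_cm, y_cm`` with
    ``marker`` in {crest, hip, ankle, toe}; the header carries
    ``frame_rate`` so times can be re-derived from frame indices.
footfall table
    ``animal, pass, limb, contact_s, liftoff_s, toe_x_cm, step_type``
    with ``limb`` in {LH, RH, LF, RF} and ``step_type`` in
    {plantar, dorsal}.  An optional leading ``condition`` column is
    preserved when present.
swim table
    ``animal, pass, limb, peak_s`` (optional ``condition``).
"""

from __future__ import annotations

import hashlib
import json
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import LIMBS, MARKERS, STEP_TYPES, MarkerTrackSet, SchemaError

__all__ = [
    "RunConfig",
    "write_marker_table",
    "read_marker_table",
    "write_footfall_table",
    "read_footfall_table",
    "write_swim_table",
    "read_swim_table",
    "config_hash",
]

_MARKER_COLS = ["animal", "pass", "frame", "time_s", "marker", "limb", "x_cm", "y_cm"]
_FOOTFALL_COLS = ["animal", "pass", "limb", "contact_s", "liftoff_s", "toe_x_cm", "step_type"]
_SWIM_COLS = ["animal", "pass", "limb", "peak_s"]


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    footfall_path: Optional[str] = None
    marker_path: Optional[str] = None
    swim_path: Optional[str] = None
    pairs: Sequence[str] = ("hindlimb", "forelimb", "homolateral", "heterolateral")
    control_label: str = "uninjured_control"
    variance_variant: str = "unpooled"
    n_permutations: int = 999
    seed: int = 0
    out_dir: str = "results"


def config_hash(obj) -> str:
    """Stable short hash of a configuration object for provenance."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write(df: pd.DataFrame, path, header: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def _read(path, schema: str) -> Tuple[pd.DataFrame, Dict[str, str]]:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        meta: Dict[str, str] = {}
        if first.startswith("#"):
            parts = first.lstrip("# ").split()
            if not parts or not parts[0].startswith(f"quadgait:{schema}"):
                raise SchemaError(
                    f"{path}: expected 'quadgait:{schema}' header, got {first!r}"
                )
            for kv in parts[1:]:
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    meta[k] = v
            body = fh.read()
        else:
            body = first + "\n" + fh.read()
        df = pd.read_csv(_io.StringIO(body))
    return df, meta


def write_marker_table(
    tracks: Dict[Tuple[int, int], Dict[str, MarkerTrackSet]],
    path,
    frame_rate: float,
) -> None:
    """Write marker trajectories keyed by (animal, pass) -> limb -> tracks."""
    rows = []
    for (animal, pass_id), by_limb in tracks.items():
        for limb, tr in by_limb.items():
            frames = np.round(tr.time_s * frame_rate).astype(int)
            for j, marker in enumerate(MARKERS):
                rows.append(
                    pd.DataFrame(
                        {
                            "animal": animal,
                            "pass": pass_id,
                            "frame": frames,
                            "time_s": tr.time_s,
                            "marker": marker,
                            "limb": limb,
                            "x_cm": tr.x[:, j],
                            "y_cm": tr.y[:, j],
                        }
                    )
                )
    df = pd.concat(rows, ignore_index=True)
    _write(df, path, f"# quadgait:marker.v1 frame_rate={frame_rate}")


def read_marker_table(path) -> Tuple[Dict[Tuple[int, int, str], MarkerTrackSet], float]:
    """Read a marker table into MarkerTrackSets keyed by (animal, pass, limb).

    Validates the schema: all columns present, the four markers present
    on every frame, strictly increasing frames per group, finite
    coordinates.  Grouping is independent of row order.
    """
    df, meta = _read(path, "marker")
    missing = [c for c in _MARKER_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"marker table missing columns {missing}")
    frame_rate = float(meta.get("frame_rate", "nan"))
    if not np.isfinite(df["x_cm"]).all() or not np.isfinite(df["y_cm"]).all():
        bad = df.index[~(np.isfinite(df["x_cm"]) & np.isfinite(df["y_cm"]))][0]
        raise SchemaError(f"non-finite coordinate at row {bad}")
    out: Dict[Tuple[int, int, str], MarkerTrackSet] = {}
    for (animal, pass_id, limb), grp in df.groupby(["animal", "pass", "limb"]):
        wide = grp.pivot_table(
            index="frame", columns="marker", values=["x_cm", "y_cm", "time_s"]
        )
        frames = wide.index.to_numpy()
        for marker in MARKERS:
            if ("x_cm", marker) not in wide.columns or wide[("x_cm", marker)].isna().any():
                miss = (
                    wide.index[wide[("x_cm", marker)].isna()][0]
                    if ("x_cm", marker) in wide.columns
                    else frames[0]
                )
                raise SchemaError(
                    f"marker {marker!r} missing at frame {miss} "
                    f"(animal={animal}, pass={pass_id}, limb={limb})"
                )
        if np.any(np.diff(frames) <= 0):
            raise SchemaError(f"non-monotone frames for animal={animal} pass={pass_id}")
        if np.isfinite(frame_rate):
            time_s = frames / frame_rate
        else:
            time_s = wide[("time_s", MARKERS[0])].to_numpy()
        x = np.column_stack([wide[("x_cm", m)].to_numpy() for m in MARKERS])
        y = np.column_stack([wide[("y_cm", m)].to_numpy() for m in MARKERS])
        out[(animal, pass_id, limb)] = MarkerTrackSet(
            limb=limb, time_s=time_s, x=x, y=y
        )
    return out, frame_rate


def write_footfall_table(df: pd.DataFrame, path) -> None:
    _write(df, path, "# quadgait:footfall.v1")


def read_footfall_table(path) -> pd.DataFrame:
    """Read and validate a footfall event table."""
    df, _ = _read(path, "footfall")
    missing = [c for c in _FOOTFALL_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"footfall table missing columns {missing}")
    bad_limb = ~df["limb"].isin(LIMBS)
    if bad_limb.any():
        raise SchemaError(f"unknown limb at row {df.index[bad_limb][0]}")
    bad_type = ~df["step_type"].isin(STEP_TYPES)
    if bad_type.any():
        raise SchemaError(f"unknown step_type at row {df.index[bad_type][0]}")
    bad_times = df["contact_s"] >= df["liftoff_s"]
    if bad_times.any():
        raise SchemaError(
            f"contact_s >= liftoff_s at row {df.index[bad_times][0]}"
        )
    return df


def write_swim_table(df: pd.DataFrame, path) -> None:
    _write(df, path, "# quadgait:swim.v1")


def read_swim_table(path) -> pd.DataFrame:
    df, _ = _read(path, "swim")
    missing = [c for c in _SWIM_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"swim table missing columns {missing}")
    return df
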