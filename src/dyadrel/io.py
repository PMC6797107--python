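"""Reading and writing trajectory tables, dyad annotations and fitted models.

Trajectory files are delimited text (comma or tab, auto-detected) with a header
row.  Column names are free and mapped onto the canonical fields ``time``,
``id``, ``x``, ``y``, ``height`` through a user-supplied column map, because
tracker exports differ in layout and units.  Internal units are always seconds
and meters.  All paths may be gzip-compressed (``.gz``); pandas handles the
decompression transparently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four social-relation categories (Bugental's coalitional / attachment /
#: mating / reciprocal domains, in the pedestrian setting).
RELATIONS = ("colleagues", "families", "couples", "friends")

#: Meta-categories for the two-stage (hierarchical) protocol.
WORK_LEISURE = ("work", "leisure")
LEISURE_RELATIONS = ("families", "couples", "friends")

#: Unit conversion factors to canonical units (seconds, meters).
_UNIT_FACTORS = {
    "s": 1.0, "sec": 1.0, "seconds": 1.0,
    "ms": 1e-3, "milliseconds": 1e-3,
    "m": 1.0, "meters": 1.0,
    "mm": 1e-3, "millimeters": 1e-3,
    "cm": 1e-2, "centimeters": 1e-2,
}


class FormatError(ValueError):
    """A file does not follow the declared dialect/column layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(eq=False)
class PedestrianTrack:
    """One pedestrian's time-stamped planar positions plus body height.

    ``t``, ``x``, ``y`` are parallel arrays in seconds / meters, sorted by
    strictly increasing time.  ``height`` is a single scalar per pedestrian,
    as produced by the tracker.
    """

    ped_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    height: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.size < 2:
            raise ValidationError(
                f"track {self.ped_id!r} needs >= 2 samples for velocity estimation"
            )
        if not (self.t.size == self.x.size == self.y.size):
            raise ValidationError(f"track {self.ped_id!r}: ragged sample arrays")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError(
                f"track {self.ped_id!r}: timestamps not strictly increasing"
            )
        if not np.isfinite(self.height) or self.height <= 0:
            raise ValidationError(f"track {self.ped_id!r}: height must be > 0")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])


@dataclass(eq=False)
class DyadRecord:
    """A pair of tracks with a ground-truth relation label and optional ages."""

    dyad_id: str
    track_a: PedestrianTrack
    track_b: PedestrianTrack
    relation: str
    age_a: float | None = None
    age_b: float | None = None

    def __post_init__(self) -> None:
        self.relation = str(self.relation).strip().lower()
        if self.relation not in RELATIONS:
            raise ValidationError(
                f"unknown relation label {self.relation!r}; expected one of {RELATIONS}"
            )
        lo = max(self.track_a.t[0], self.track_b.t[0])
        hi = min(self.track_a.t[-1], self.track_b.t[-1])
        if hi - lo < 1.0:
            raise ValidationError(
                f"dyad {self.dyad_id!r}: tracks overlap for {hi - lo:.3f} s (< 1 s)"
            )


def _unit_factor(unit: str) -> float:
    try:
        return _UNIT_FACTORS[unit.lower()]
    except KeyError:
        raise FormatError(f"unknown unit {unit!r}") from None


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # auto-detect comma vs tab from the header line
    return pd.read_csv(path, sep=None, engine="python")


def read_tracks(
    path: str | Path,
    column_map: Mapping[str, str],
    units: Mapping[str, str] | None = None,
) -> dict[str, PedestrianTrack]:
    """Read a trajectory table into one :class:`PedestrianTrack` per pedestrian.

    Parameters
    ----------
    path
        Delimited-text file (optionally ``.gz``) with a header row.
    column_map
        Maps canonical fields ``{"time", "id", "x", "y", "height"}`` to the
        column names present in the file.
    units
        Optional per-field unit declarations (e.g. ``{"x": "mm"}``); values are
        converted to seconds / meters.  Fields default to seconds and meters.

    Returns
    -------
    dict
        ``ped_id -> PedestrianTrack``, samples sorted by time.
    """
    required = {"time", "id", "x", "y", "height"}
    missing_fields = required - set(column_map)
    if missing_fields:
        raise ValidationError(
            f"column_map lacks required fields: {sorted(missing_fields)}"
        )
    df = _read_table(path)
    for fieldname in required:
        col = column_map[fieldname]
        if col not in df.columns:
            raise FormatError(f"file {path} is missing mapped column {col!r}")

    units = dict(units or {})
    fac = {f: _unit_factor(units[f]) if f in units else 1.0 for f in required}

    sub = pd.DataFrame(
        {
            "time": pd.to_numeric(df[column_map["time"]], errors="coerce") * fac["time"],
            "id": df[column_map["id"]].astype(str),
            "x": pd.to_numeric(df[column_map["x"]], errors="coerce") * fac["x"],
            "y": pd.to_numeric(df[column_map["y"]], errors="coerce") * fac["y"],
            "height": pd.to_numeric(df[column_map["height"]], errors="coerce")
            * fac["height"],
        }
    )
    if not np.isfinite(sub[["time", "x", "y", "height"]].to_numpy()).all():
        raise FormatError(f"file {path} contains non-finite coordinates")

    tracks: dict[str, PedestrianTrack] = {}
    for ped_id, grp in sub.groupby("id", sort=False):
        grp = grp.sort_values("time", kind="stable")
        t = grp["time"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"pedestrian {ped_id!r}: duplicate or non-monotone timestamps"
            )
        tracks[str(ped_id)] = PedestrianTrack(
            ped_id=str(ped_id),
            t=t,
            x=grp["x"].to_numpy(),
            y=grp["y"].to_numpy(),
            height=float(grp["height"].iloc[0]),
        )
    return tracks


def read_dyads(
    path: str | Path, tracks: Mapping[str, PedestrianTrack]
) -> list[DyadRecord]:
    """Read a dyad annotation table and attach the referenced tracks.

    Expected columns: ``dyad_id, ped_a, ped_b, relation[, age_a, age_b]``.
    Rows referencing unknown pedestrian ids are skipped with a logged warning;
    unknown relation labels are fatal.
    """
    df = _read_table(path)
    needed = {"dyad_id", "ped_a", "ped_b", "relation"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"dyad file {path} is missing columns {sorted(missing)}")

    dyads: list[DyadRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        rel = str(row.relation).strip().lower()
        if rel not in RELATIONS:
            raise ValidationError(
                f"unknown relation label {row.relation!r} for dyad {row.dyad_id!r}"
            )
        pa, pb = str(row.ped_a), str(row.ped_b)
        if pa not in tracks or pb not in tracks:
            n_skipped += 1
            continue
        age_a = getattr(row, "age_a", None)
        age_b = getattr(row, "age_b", None)
        dyads.append(
            DyadRecord(
                dyad_id=str(row.dyad_id),
                track_a=tracks[pa],
                track_b=tracks[pb],
                relation=rel,
                age_a=None if age_a is None or pd.isna(age_a) else float(age_a),
                age_b=None if age_b is None or pd.isna(age_b) else float(age_b),
            )
        )
    if n_skipped:
        logger.warning("read_dyads: skipped %d rows referencing unknown ids", n_skipped)
    return dyads


def write_tracks(
    tracks: Sequence[PedestrianTrack] | Mapping[str, PedestrianTrack],
    path: str | Path,
) -> None:
    """Write tracks in the canonical layout read back by :func:`read_tracks`."""
    if isinstance(tracks, Mapping):
        tracks = list(tracks.values())
    frames = [
        pd.DataFrame(
            {"time": tr.t, "ped_id": tr.ped_id, "x": tr.x, "y": tr.y,
             "height": tr.height}
        )
        for tr in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_dyads(dyads: Sequence[DyadRecord], path: str | Path) -> None:
    """Write the dyad annotation table matching :func:`read_dyads`."""
    pd.DataFrame(
        {
            "dyad_id": [d.dyad_id for d in dyads],
            "ped_a": [d.track_a.ped_id for d in dyads],
            "ped_b": [d.track_b.ped_id for d in dyads],
            "relation": [d.relation for d in dyads],
            "age_a": [d.age_a for d in dyads],
            "age_b": [d.age_b for d in dyads],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model (de)serialization


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted relation model to JSON (text, full float repr)."""
    payload = {
        "relations": list(model.relations),
        "metadata": dict(model.metadata),
        "pdfs": {
            rel: {
                obs: {
                    "lo": pdf.lo,
                    "hi": pdf.hi,
                    "n_bins": pdf.n_bins,
                    "mass": [repr(float(m)) for m in pdf.mass],
                }
                for obs, pdf in per_obs.items()
            }
            for rel, per_obs in model.pdfs.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path):
    """Load a model written by :func:`save_model`, validating its invariants."""
    from .distributions import BinnedPDF, RelationModel

    try:
        payload = json.loads(Path(path).read_text())
        relations = tuple(payload["relations"])
        pdfs = {
            rel: {
                obs: BinnedPDF(
                    lo=float(entry["lo"]),
                    hi=float(entry["hi"]),
                    n_bins=int(entry["n_bins"]),
                    mass=np.array([float(m) for m in entry["mass"]]),
                )
                for obs, entry in per_obs.items()
            }
            for rel, per_obs in payload["pdfs"].items()
        }
        metadata = payload.get("metadata", {})
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"corrupted model file {path}: {exc}") from exc
    return RelationModel(relations=relations, pdfs=pdfs, metadata=metadata)
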