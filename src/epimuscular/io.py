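"""File round-tripping: stiffness YAML, isometric/waveform CSV, JSON stats.

All numeric columns carry units in their names.  Stiffness is serialised in
mN/mm (the conventional reporting scale); forces in N; positions in mm.
Unit conversion happens only here — the rest of the package works in N and
mm.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import PATHWAYS, PiecewiseStiffness, StiffnessSet
from .estimation import CHANNELS, ForceWaveform, IsometricForceTable
from .exceptions import StructuralError
from .prediction import AgreementStats, PredictionResult

_TABLE_META = ("animal_id", "group", "condition", "mode")
_TABLE_VALUE_COLUMNS = tuple(
    f"{state}_{ch}_N" for ch in CHANNELS for state in ("passive", "total")
)


def stiffness_to_dict(sset: StiffnessSet) -> dict:
    out: dict = {"group": sset.group, "c": sset.c, "pathways": {}}
    for name in PATHWAYS:
        pw = sset.pathways[name]
        entry = {
            "breakpoints_mm": list(pw.breakpoints),
            "K_mN_per_mm": [1e3 * v for v in pw.values],
        }
        if pw.negative_values is not None:
            entry["K_negative_mN_per_mm"] = [1e3 * v for v in pw.negative_values]
        out["pathways"][name] = entry
    return out


def _group_label(value) -> str:
    # YAML 1.1 parses a bare NO as boolean False; recover the group label.
    if value is False:
        return "NO"
    return "" if value is None else str(value)


def stiffness_from_dict(doc: dict) -> StiffnessSet:
    try:
        raw = doc["pathways"]
    except (KeyError, TypeError) as exc:
        raise StructuralError("stiffness document lacks a 'pathways' mapping") from exc
    pathways = {}
    for name in PATHWAYS:
        if name not in raw:
            raise StructuralError(f"stiffness document lacks pathway {name!r}")
        entry = raw[name]
        neg = entry.get("K_negative_mN_per_mm")
        pathways[name] = PiecewiseStiffness(
            pathway=name,
            values=tuple(1e-3 * float(v) for v in entry["K_mN_per_mm"]),
            breakpoints=tuple(float(b) for b in entry["breakpoints_mm"]),
            negative_values=(
                None if neg is None else tuple(1e-3 * float(v) for v in neg)
            ),
            group=_group_label(doc.get("group")) or None,
        )
    return StiffnessSet(
        pathways=pathways,
        group=_group_label(doc.get("group")),
        c=float(doc.get("c", 0.9)),
    )


def write_stiffness_yaml(sset: StiffnessSet, path: "str | Path | IO[str]") -> None:
    doc = stiffness_to_dict(sset)
    if hasattr(path, "write"):
        yaml.safe_dump(doc, path, sort_keys=False)
    else:
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_stiffness_yaml(path: "str | Path | IO[str]") -> StiffnessSet:
    text = path.read() if hasattr(path, "read") else Path(path).read_text()
    return stiffness_from_dict(yaml.safe_load(text))


def tables_to_frame(tables: Iterable[IsometricForceTable]) -> pd.DataFrame:
    """Flatten isometric tables to one tidy frame (one row per
    animal × condition × position)."""
    frames = []
    for t in tables:
        df = t.data.reset_index()
        df.insert(0, "animal_id", t.animal_id)
        df.insert(1, "group", t.group)
        df.insert(2, "condition", t.condition)
        df.insert(3, "mode", t.mode)
        frames.append(df)
    if not frames:
        raise StructuralError("no tables to serialise")
    return pd.concat(frames, ignore_index=True)


def write_isometric_csv(
    tables: Iterable[IsometricForceTable], path: "str | Path"
) -> None:
    tables_to_frame(tables).to_csv(path, index=False, float_format="%.9g")


def read_isometric_csv(path: "str | Path") -> list[IsometricForceTable]:
    """Read isometric tables; rows may arrive in any order and are
    normalised by position.  Missing columns raise a format error naming
    the offending column."""
    df = pd.read_csv(path)
    required = _TABLE_META + ("position_mm",) + _TABLE_VALUE_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StructuralError(f"isometric CSV missing column(s): {missing}")
    tables = []
    for (animal, group, condition, mode), sub in df.groupby(
        ["animal_id", "group", "condition", "mode"], sort=True
    ):
        data = (
            sub.set_index("position_mm")[list(_TABLE_VALUE_COLUMNS)]
            .sort_index()
            .astype(float)
        )
        tables.append(
            IsometricForceTable(
                data=data,
                condition=str(condition),
                group=str(group),
                animal_id=str(animal),
                mode=str(mode),
            )
        )
    return tables


def write_waveform_csv(
    waveform: ForceWaveform, csv_path: "str | Path", sidecar_path: "str | Path"
) -> None:
    df = pd.DataFrame({"time_s": waveform.time_s})
    for ch in CHANNELS:
        df[f"{ch}_N"] = waveform.forces_N[ch]
    df.to_csv(csv_path, index=False, float_format="%.9g")
    meta = {
        "stim_onset_s": waveform.stim_onset_s,
        "stim_offset_s": waveform.stim_offset_s,
        "twitch_times_s": list(waveform.twitch_times_s),
        "position_mm": waveform.position_mm,
        "condition": waveform.condition,
        "group": waveform.group,
        "animal_id": waveform.animal_id,
    }
    Path(sidecar_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_waveform_csv(
    csv_path: "str | Path", sidecar_path: "str | Path"
) -> ForceWaveform:
    df = pd.read_csv(csv_path)
    missing = [
        c for c in ["time_s"] + [f"{ch}_N" for ch in CHANNELS] if c not in df.columns
    ]
    if missing:
        raise StructuralError(f"waveform CSV missing column(s): {missing}")
    meta = yaml.safe_load(Path(sidecar_path).read_text())
    return ForceWaveform(
        time_s=df["time_s"].to_numpy(),
        forces_N={ch: df[f"{ch}_N"].to_numpy() for ch in CHANNELS},
        stim_onset_s=float(meta["stim_onset_s"]),
        stim_offset_s=float(meta["stim_offset_s"]),
        twitch_times_s=tuple(float(t) for t in meta.get("twitch_times_s", ())),
        position_mm=float(meta.get("position_mm", 0.0)),
        condition=str(meta.get("condition", "intact")),
        group=str(meta.get("group", "")),
        animal_id=str(meta.get("animal_id", "")),
    )


def write_prediction_csv(result: PredictionResult, path: "str | Path") -> None:
    pd.DataFrame(
        {"dp_prox_mm": result.dp_mm, "delta_f_lgpl_mod_N": result.delta_f_N}
    ).to_csv(path, index=False, float_format="%.9g")


def write_agreement_json(stats: AgreementStats, path: "str | Path") -> None:
    Path(path).write_text(json.dumps(stats.to_dict(), indent=2, sort_keys=True) + "\n")


def read_series_csv(path: "str | Path", column: str) -> np.ndarray:
    df = pd.read_csv(path)
    if column not in df.columns:
        raise StructuralError(f"CSV {path} lacks column {column!r}")
    return df[column].to_numpy(dtype=float)


def write_estimates_csv(frame: pd.DataFrame, path: "str | Path") -> None:
    frame.to_csv(path, float_format="%.9g")


def load_r_yaml(path: "str | Path | IO[str]") -> tuple[float, ...]:
    text = path.read() if hasattr(path, "read") else Path(path).read_text()
    doc = yaml.safe_load(text)
    try:
        return tuple(float(v) for v in doc["r"])
    except (KeyError, TypeError) as exc:
        raise StructuralError("scale-factor document lacks an 'r' list") from exc


def parse_r(text: str) -> tuple[float, ...]:
    """Parse a comma-separated r vector from the command line."""
    try:
        return tuple(float(v) for v in text.split(","))
    except ValueError as exc:
        raise StructuralError(f"cannot parse r vector from {text!r}") from exc
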