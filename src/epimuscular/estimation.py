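"""Calibration pipeline: from tendon force recordings to pathway stiffness.

The calibration experiment repositions both LG+PL tendons together over a
±3 mm range in 1-mm steps while SO is held fixed, and repeats the protocol
under three resection conditions: ``intact`` (all pathways present),
``postI`` (intermuscular myofascial tissue resected) and ``postII``
(additionally the SO neurovascular tract NV1 resected).  Solving the static
force balance across conditions yields per-position estimates of the force
carried by each pathway:

    F_INT = dF_intact - c * dF_postI + (c - 1) * dF_postII
    F_NV1 = dF_postI - dF_postII
    F_NV2 = dF_postII

where ``dF`` is the LG+PL proximo-distal force difference in each condition
and ``c`` (default 0.9) is the NV1 length ratio before/after resection of
the myofascial linkages.  Segment stiffnesses are the force increments per
1-mm displacement band; averaging mirrored positive/negative slopes (odd
symmetry about the reference position) is the default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CONDITIONS,
    PATHWAYS,
    PiecewiseStiffness,
    PositionProtocol,
    StiffnessSet,
)
from .exceptions import (
    ExtractionError,
    InvalidInputError,
    ParameterError,
    StructuralError,
)

log = logging.getLogger(__name__)

#: Tendon force channels, in canonical column order.
CHANNELS = ("f_so_dist", "f_lgpl_prox", "f_lgpl_dist")

#: Default extraction window (ms), matching the experimental analysis.
DEFAULT_WINDOW_MS = 50.0

_POSITION_TOL = 1e-9


@dataclass(frozen=True)
class ForceWaveform:
    """Simultaneously recorded tendon force–time series for one contraction.

    Forces are tetanic recordings at the three measured tendons, with two
    conditioning twitches preceding the tetanus.  Time must be uniformly
    sampled and strictly increasing; the stimulation window must lie inside
    the recording.
    """

    time_s: np.ndarray
    forces_N: Mapping[str, np.ndarray]
    stim_onset_s: float
    stim_offset_s: float
    twitch_times_s: tuple[float, ...] = ()
    position_mm: float = 0.0
    condition: str = "intact"
    group: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        object.__setattr__(self, "time_s", t)
        if t.ndim != 1 or t.size < 2:
            raise StructuralError("time axis must be a 1-D array of >= 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise StructuralError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise StructuralError("time must be uniformly sampled")
        forces = {}
        for ch in CHANNELS:
            if ch not in self.forces_N:
                raise StructuralError(f"missing force channel {ch!r}")
            f = np.asarray(self.forces_N[ch], dtype=float)
            if f.shape != t.shape:
                raise StructuralError(f"channel {ch!r} length mismatch")
            if not np.all(np.isfinite(f)):
                raise InvalidInputError(f"channel {ch!r} contains non-finite values")
            forces[ch] = f
        object.__setattr__(self, "forces_N", forces)
        if not (t[0] <= self.stim_onset_s < self.stim_offset_s <= t[-1]):
            raise StructuralError("stimulation window must lie inside the recording")

    @property
    def dt_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])


@dataclass(frozen=True)
class IsometricExtraction:
    """Passive and total isometric force (N) for one channel."""

    passive_N: float
    total_N: float


def extract_isometric(
    waveform: ForceWaveform, window_ms: float = DEFAULT_WINDOW_MS
) -> dict[str, IsometricExtraction]:
    """Extract passive and total isometric forces from a tetanic recording.

    Passive force is the mean over the ``window_ms`` immediately preceding
    tetanic onset; total force is the mean over the last ``window_ms`` of
    the tetanic stimulation.  If a conditioning twitch falls inside the
    passive window the window is shifted to end just before that twitch
    (logged as a warning).
    """
    if window_ms <= 0:
        raise ParameterError("window_ms must be positive")
    w = window_ms * 1e-3
    t = waveform.time_s
    if waveform.stim_offset_s - waveform.stim_onset_s < w:
        raise ExtractionError(
            "stimulation window shorter than the extraction window"
        )

    passive_end = waveform.stim_onset_s
    # Shift the passive window ahead of any twitch that intrudes into it.
    for _ in range(len(waveform.twitch_times_s) + 1):
        intruding = [
            tw
            for tw in waveform.twitch_times_s
            if passive_end - w <= tw < passive_end
        ]
        if not intruding:
            break
        new_end = min(intruding)
        warnings.warn(
            f"twitch at {new_end:.3f} s overlaps the passive window; "
            f"shifting window to end at {new_end:.3f} s",
            stacklevel=2,
        )
        log.warning("passive window shifted from %.3f to %.3f s", passive_end, new_end)
        passive_end = new_end
    if passive_end - w < t[0]:
        raise ExtractionError(
            "not enough pre-stimulation data for the passive window"
        )

    def window_mean(f: np.ndarray, start: float, end: float) -> float:
        i0 = int(np.searchsorted(t, start - _POSITION_TOL, side="left"))
        i1 = int(np.searchsorted(t, end - _POSITION_TOL, side="left"))
        if i1 <= i0:
            raise ExtractionError("extraction window contains no samples")
        return float(np.mean(f[i0:i1]))

    out: dict[str, IsometricExtraction] = {}
    for ch in CHANNELS:
        f = waveform.forces_N[ch]
        passive = window_mean(f, passive_end - w, passive_end)
        total = window_mean(f, waveform.stim_offset_s - w, waveform.stim_offset_s)
        out[ch] = IsometricExtraction(passive_N=passive, total_N=total)
    return out


_TABLE_COLUMNS = tuple(
    f"{state}_{ch}_N" for ch in CHANNELS for state in ("passive", "total")
)


@dataclass
class IsometricForceTable:
    """Per-position passive/total tendon forces for one animal & condition.

    ``data`` is indexed by ``position_mm`` (sorted ascending) with one
    column per (state, channel): ``passive_f_so_dist_N`` … ``total_f_lgpl_dist_N``.
    """

    data: pd.DataFrame
    condition: str
    group: str
    animal_id: str
    mode: str = "both"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise StructuralError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.mode not in ("both", "proximal_only"):
            raise StructuralError(f"unknown protocol mode {self.mode!r}")
        df = self.data
        missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise StructuralError(f"isometric table missing column(s) {missing}")
        df = df[list(_TABLE_COLUMNS)].astype(float).sort_index()
        if df.index.has_duplicates:
            raise StructuralError("duplicate positions in isometric table")
        if not np.all(np.isfinite(df.to_numpy())):
            raise InvalidInputError("isometric table contains non-finite forces")
        for ch in CHANNELS:
            if np.any(
                df[f"passive_{ch}_N"].to_numpy()
                > df[f"total_{ch}_N"].to_numpy() + 1e-9
            ):
                raise InvalidInputError(
                    f"passive force exceeds total force on channel {ch!r}"
                )
        self.data = df

    @property
    def positions_mm(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=float)

    @property
    def protocol(self) -> PositionProtocol:
        return PositionProtocol(positions=tuple(self.positions_mm), mode=self.mode)

    def channel(self, channel: str, state: str = "total") -> pd.Series:
        col = f"{state}_{channel}_N"
        if col not in self.data.columns:
            raise StructuralError(f"no column {col!r}")
        return self.data[col]


def _check_state(state: str) -> None:
    if state not in ("passive", "total"):
        raise ParameterError(f"state must be 'passive' or 'total', got {state!r}")


def delta_F_LGPL(table: IsometricForceTable, state: str = "total") -> pd.Series:
    """LG+PL proximo-distal force difference (N) per position.

    Positive values indicate a higher proximal force, i.e. net force
    entering LG+PL proximally and leaving through epimuscular pathways.
    """
    _check_state(state)
    d = table.channel("f_lgpl_prox", state) - table.channel("f_lgpl_dist", state)
    return d.rename("delta_f_lgpl_N")


def delta_F_SO(table: IsometricForceTable, state: str = "total") -> pd.Series:
    """Change of SO distal tendon force (N) relative to the reference
    position, at which the change is zero by definition."""
    _check_state(state)
    f = table.channel("f_so_dist", state)
    ref = f.index[np.isclose(f.index.to_numpy(dtype=float), 0.0)]
    if len(ref) != 1:
        raise StructuralError("table has no unique reference position (0 mm)")
    return (f - f.loc[ref[0]]).rename("delta_f_so_N")


@dataclass(frozen=True)
class PathwayForceEstimates:
    """Per-position estimates of the force carried by each pathway (N)."""

    positions_mm: np.ndarray
    f_int_N: np.ndarray
    f_nv1_N: np.ndarray
    f_nv2_N: np.ndarray
    c: float
    group: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_mm, dtype=float)
        object.__setattr__(self, "positions_mm", pos)
        for name in ("f_int_N", "f_nv1_N", "f_nv2_N"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != pos.shape:
                raise StructuralError(f"{name} length mismatch with positions")
            object.__setattr__(self, name, arr)

    def pathway(self, name: str) -> np.ndarray:
        return {"INT": self.f_int_N, "NV1": self.f_nv1_N, "NV2": self.f_nv2_N}[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"INT": self.f_int_N, "NV1": self.f_nv1_N, "NV2": self.f_nv2_N},
            index=pd.Index(self.positions_mm, name="position_mm"),
        )


def _aligned(
    name: str, series: "pd.Series | np.ndarray | Sequence[float]"
) -> np.ndarray:
    arr = (
        series.to_numpy(dtype=float)
        if isinstance(series, pd.Series)
        else np.asarray(series, dtype=float)
    )
    if arr.ndim != 1:
        raise StructuralError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


def estimate_pathway_forces(
    delta_intact: "pd.Series | Sequence[float]",
    delta_postI: "pd.Series | Sequence[float]",
    delta_postII: "pd.Series | Sequence[float]",
    c: float = 0.9,
    positions_mm: Sequence[float] | None = None,
    group: str = "",
) -> PathwayForceEstimates:
    """Solve the three-condition force balance for the pathway forces.

    The estimator is linear in each input series and satisfies the exact
    conservation identity ``F_INT + F_NV1 + F_NV2 = dF_intact + (1 - c) * F_NV1``.
    """
    if not (0.0 < c <= 1.0):
        raise ParameterError(f"c must lie in (0, 1], got {c}")
    di = _aligned("delta_intact", delta_intact)
    d1 = _aligned("delta_postI", delta_postI)
    d2 = _aligned("delta_postII", delta_postII)
    if not (di.shape == d1.shape == d2.shape):
        raise StructuralError("the three condition series must be aligned")
    if positions_mm is None:
        if isinstance(delta_intact, pd.Series):
            positions_mm = delta_intact.index.to_numpy(dtype=float)
        else:
            raise StructuralError("positions_mm required for array inputs")
    pos = np.asarray(positions_mm, dtype=float)
    f_int = di - c * d1 + d2 * (c - 1.0)
    f_nv1 = d1 - d2
    f_nv2 = d2.copy()
    return PathwayForceEstimates(
        positions_mm=pos, f_int_N=f_int, f_nv1_N=f_nv1, f_nv2_N=f_nv2, c=c, group=group
    )


def _value_at(pos: np.ndarray, vals: np.ndarray, p: float) -> float:
    hits = np.flatnonzero(np.isclose(pos, p, atol=1e-9))
    if hits.size != 1:
        raise StructuralError(f"no measurement at position {p} mm")
    return float(vals[hits[0]])


def fit_piecewise_stiffness(
    estimates: PathwayForceEstimates,
    breakpoints: Sequence[float] = (0.0, 1.0, 2.0, 3.0),
    symmetry: bool = True,
) -> StiffnessSet:
    """Fit segment stiffnesses to the per-position pathway force estimates.

    Each segment stiffness is the force increment across the displacement
    band divided by the band width.  With ``symmetry`` (default) the
    positive-side slope is averaged with the mirrored negative-side slope
    (odd symmetry about the reference); otherwise the negative side is
    fitted with its own segments.
    """
    bps = tuple(float(b) for b in breakpoints)
    pos = estimates.positions_mm
    pathways: dict[str, PiecewiseStiffness] = {}
    for name in PATHWAYS:
        vals = estimates.pathway(name)
        k_pos, k_neg = [], []
        for j in range(len(bps) - 1):
            lo, hi = bps[j], bps[j + 1]
            width = hi - lo
            if width <= 0:
                raise ParameterError("zero-width stiffness segment")
            k_pos.append(
                (_value_at(pos, vals, hi) - _value_at(pos, vals, lo)) / width
            )
            k_neg.append(
                (_value_at(pos, vals, -lo) - _value_at(pos, vals, -hi)) / width
            )
        if symmetry:
            k = tuple(0.5 * (a + b) for a, b in zip(k_pos, k_neg))
            pathways[name] = PiecewiseStiffness(
                pathway=name, values=k, breakpoints=bps, group=estimates.group or None
            )
        else:
            pathways[name] = PiecewiseStiffness(
                pathway=name,
                values=tuple(k_pos),
                breakpoints=bps,
                negative_values=tuple(k_neg),
                group=estimates.group or None,
            )
    return StiffnessSet(pathways=pathways, group=estimates.group, c=estimates.c)


def c_sensitivity(
    delta_intact: "pd.Series | Sequence[float]",
    delta_postI: "pd.Series | Sequence[float]",
    delta_postII: "pd.Series | Sequence[float]",
    c_grid: Sequence[float] | None = None,
    c_ref: float = 0.9,
    positions_mm: Sequence[float] | None = None,
) -> pd.Series:
    """Sensitivity of the intermuscular force estimate to the parameter c.

    For each c in the grid, returns the RMSE over positions of
    ``F_INT(c) - F_INT(c_ref)`` expressed as a percentage of the mean
    absolute intermuscular force at ``c_ref``.  Analytically the curve is
    ``|c - c_ref| * RMS(F_NV1) / mean|F_INT(c_ref)| * 100``.
    """
    if c_grid is None:
        c_grid = np.round(np.arange(0.05, 1.0 + 1e-9, 0.05), 10)
    ref = estimate_pathway_forces(
        delta_intact, delta_postI, delta_postII, c=c_ref, positions_mm=positions_mm
    )
    denom = float(np.mean(np.abs(ref.f_int_N)))
    if denom == 0.0:
        raise ParameterError(
            "mean |F_INT| at the reference c is zero; sensitivity undefined"
        )
    out = {}
    for c in c_grid:
        est = estimate_pathway_forces(
            delta_intact, delta_postI, delta_postII, c=float(c), positions_mm=positions_mm
        )
        rmse = float(np.sqrt(np.mean((est.f_int_N - ref.f_int_N) ** 2)))
        out[float(c)] = 100.0 * rmse / denom
    return pd.Series(out, name="rmse_pct").rename_axis("c")


def estimate_r(
    full: PiecewiseStiffness, proximal_only: PiecewiseStiffness
) -> np.ndarray:
    """Per-segment ratio of intermuscularly transmitted force under
    proximal-only loading to that under proximal-plus-distal loading.

    Both inputs must share segment structure; full-protocol segment values
    must be non-zero.
    """
    if full.breakpoints != proximal_only.breakpoints:
        raise StructuralError("segment structures must match")
    denom = np.asarray(full.values, dtype=float)
    numer = np.asarray(proximal_only.values, dtype=float)
    if np.any(denom == 0.0):
        raise ParameterError("full-protocol segment stiffness of zero: r undefined")
    return numer / denom


def pathway_ratios(
    estimates: PathwayForceEstimates, f_prox_mean_N: float
) -> pd.DataFrame:
    """Signed pathway forces as a percentage of the mean LG+PL proximal
    tendon force, per position, with a ``net`` column for their sum."""
    if not (f_prox_mean_N > 0.0):
        raise ParameterError("mean proximal force must be positive")
    frame = estimates.to_frame() * (100.0 / f_prox_mean_N)
    frame["net"] = frame[list(PATHWAYS)].sum(axis=1)
    return frame


@dataclass(frozen=True)
class GroupCalibration:
    """Result of calibrating one connectivity group."""

    stiffness: StiffnessSet
    per_animal: Mapping[str, StiffnessSet]
    estimates: Mapping[str, PathwayForceEstimates]
    f_prox_mean_N: float
    postII_animals: tuple[str, ...] = ()


def _mean_stiffness(
    sets: Sequence[StiffnessSet], group: str, c: float
) -> StiffnessSet:
    bps = sets[0].breakpoints
    pathways: dict[str, PiecewiseStiffness] = {}
    for name in PATHWAYS:
        vals = np.mean([s.pathways[name].values for s in sets], axis=0)
        negs = [s.pathways[name].negative_values for s in sets]
        neg = None
        if all(n is not None for n in negs):
            neg = tuple(np.mean(negs, axis=0))
        pathways[name] = PiecewiseStiffness(
            pathway=name,
            values=tuple(vals),
            breakpoints=bps,
            negative_values=neg,
            group=group,
        )
    return StiffnessSet(pathways=pathways, group=group, c=c)


def calibrate_group(
    tables: Iterable[IsometricForceTable],
    c: float = 0.9,
    breakpoints: Sequence[float] = (0.0, 1.0, 2.0, 3.0),
    symmetry: bool = True,
    state: str = "total",
    allow_passive: bool = False,
    postII_delta: "pd.Series | None" = None,
) -> GroupCalibration:
    """Full calibration of one group of animals.

    Per-animal pathway forces are estimated from that animal's intact and
    post-I series together with a group-level post-II series (the complete
    isolation was feasible in a single animal only, so its series is shared
    across the group; ``postII_delta`` can supply a series borrowed from
    another group).  Per-animal stiffness fits are then averaged across
    animals, mirroring mean ± SD reporting of group results.

    Stiffness estimation is restricted to the active (total-force) state:
    passive force differences are not balanced by the measured SO tendon
    and would confound the pathway estimates.  ``allow_passive=True``
    overrides this guard with a logged warning.
    """
    _check_state(state)
    if state == "passive":
        if not allow_passive:
            raise ParameterError(
                "stiffness estimation on passive forces is disabled; "
                "pass allow_passive=True to override"
            )
        warnings.warn(
            "estimating stiffness from passive forces: the lumped model "
            "assumptions do not hold in the passive state",
            stacklevel=2,
        )
        log.warning("passive-state estimation override in effect")

    by_animal: dict[str, dict[str, IsometricForceTable]] = {}
    groups = set()
    for t in tables:
        groups.add(t.group)
        slot = by_animal.setdefault(t.animal_id, {})
        if t.condition in slot:
            raise StructuralError(
                f"duplicate condition {t.condition!r} for animal {t.animal_id!r}"
            )
        slot[t.condition] = t
    if len(groups) != 1:
        raise StructuralError(f"tables span multiple groups: {sorted(groups)}")
    group = groups.pop()

    postII_sources = tuple(
        a for a, conds in sorted(by_animal.items()) if "postII" in conds
    )
    if postII_delta is None:
        if not postII_sources:
            raise StructuralError(
                "no post-II table in this group and no postII_delta supplied"
            )
        series = [
            delta_F_LGPL(by_animal[a]["postII"], state) for a in postII_sources
        ]
        postII_delta = pd.concat(series, axis=1).mean(axis=1)

    per_animal: dict[str, StiffnessSet] = {}
    per_estimates: dict[str, PathwayForceEstimates] = {}
    prox_means = []
    for animal, conds in sorted(by_animal.items()):
        if "intact" not in conds or "postI" not in conds:
            continue
        d_int = delta_F_LGPL(conds["intact"], state)
        d_p1 = delta_F_LGPL(conds["postI"], state)
        if not np.array_equal(d_int.index.to_numpy(), d_p1.index.to_numpy()) or (
            not np.array_equal(d_int.index.to_numpy(), postII_delta.index.to_numpy())
        ):
            raise StructuralError(
                f"condition protocols differ for animal {animal!r}"
            )
        est = estimate_pathway_forces(d_int, d_p1, postII_delta, c=c, group=group)
        per_estimates[animal] = est
        per_animal[animal] = fit_piecewise_stiffness(
            est, breakpoints=breakpoints, symmetry=symmetry
        )
        prox_means.append(
            float(conds["intact"].channel("f_lgpl_prox", state).mean())
        )
    if not per_animal:
        raise StructuralError("no animal has both intact and post-I tables")

    stiffness = _mean_stiffness(list(per_animal.values()), group=group, c=c)
    return GroupCalibration(
        stiffness=stiffness,
        per_animal=per_animal,
        estimates=per_estimates,
        f_prox_mean_N=float(np.mean(prox_means)),
        postII_animals=postII_sources,
    )
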