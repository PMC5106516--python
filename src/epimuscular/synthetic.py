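"""Synthetic in situ experiment: waveforms, calibration and testing data.

No public recordings of the rat plantar-flexor experiment exist, so this
module emulates it from a known ground truth.  Given a stiffness set, it
produces the tendon forces that the three-condition resection protocol
would measure:

* ``intact``  — dF_LGPL = F_INT + c * F_NV1 + F_NV2.  The factor ``c``
  appears because the ground-truth NV1 stiffness describes the tract after
  the myofascial linkages have been resected (the state in which it is
  observable in isolation); while those linkages are present the tract
  operates at ``c`` times that length, transmitting ``c`` times the force.
  With this convention the three-condition estimator inverts the generator
  exactly.
* ``postI``   — the intermuscular interface is resected: dF = F_NV1 + F_NV2.
* ``postII``  — NV1 additionally resected: dF = F_NV2.

The SO distal tendon receives a configurable fraction (default 0.3) of the
force routed through INT and NV1; the remainder exits through the intact
proximal SO insertion and other unmeasured structures.  NV2 leads force
outside the synergistic pair and never loads SO.

Waveform synthesis is schematic: a flat passive baseline, two conditioning
twitches, a fast rise to a flat tetanic plateau, and an exponential
relaxation.  Only the 50-ms extraction windows are load-bearing; the
transients are cosmetic and are kept clear of those windows by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import PositionProtocol, StiffnessSet, forward_delta_F
from .estimation import CHANNELS, ForceWaveform, IsometricForceTable
from .exceptions import ParameterError, StructuralError


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and acquisition parameters for a synthetic experiment.

    Baseline plateau forces default to the in situ means at the reference
    position (LG+PL proximal 11.5 N, SO distal 1.3 N); the tetanus lasts
    500 ms with conditioning twitches 1.5 and 1.0 s before it.  Noise is
    additive i.i.d. Gaussian per extracted force (per channel, position and
    condition), with SD of the order of the between-animal variability.
    """

    truth: StiffnessSet
    r: tuple[float, ...] | None = None
    n_animals: int = 7
    noise_sd_N: float = 0.05
    baseline_lgpl_prox_N: float = 11.5
    baseline_so_N: float = 1.3
    passive_lgpl_N: float = 0.3
    passive_so_N: float = 0.1
    so_coupling: float = 0.3
    protocol: PositionProtocol = field(default_factory=PositionProtocol)
    sampling_hz: float = 1000.0
    tetanus_onset_s: float = 2.0
    tetanus_duration_s: float = 0.5
    twitch_lead_s: tuple[float, float] = (1.5, 1.0)
    twitch_duration_s: float = 0.1
    record_duration_s: float = 3.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ParameterError("n_animals must be >= 1")
        if self.noise_sd_N < 0:
            raise ParameterError("noise SD must be non-negative")
        for name in ("baseline_lgpl_prox_N", "baseline_so_N"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not (0.0 <= self.so_coupling <= 1.0):
            raise ParameterError("so_coupling must lie in [0, 1]")
        if self.r is not None:
            r = tuple(float(v) for v in self.r)
            if len(r) != self.truth.n_segments:
                raise StructuralError(
                    f"r needs {self.truth.n_segments} entries, got {len(r)}"
                )
            object.__setattr__(self, "r", r)
        span = self.truth.span_mm
        pos = self.protocol.positions
        if max(abs(pos[0]), abs(pos[-1])) > span:
            raise StructuralError(
                "protocol positions exceed the ground-truth stiffness span"
            )
        last_twitch_end = (
            self.tetanus_onset_s - min(self.twitch_lead_s) + self.twitch_duration_s
        )
        if last_twitch_end > self.tetanus_onset_s - 0.05:
            raise ParameterError(
                "twitch would overlap the 50-ms passive extraction window"
            )
        if self.record_duration_s < self.tetanus_onset_s + self.tetanus_duration_s:
            raise ParameterError("recording ends before the tetanus does")


def condition_deltas(
    truth: StiffnessSet, p_r: float, condition: str, so_coupling: float = 0.3
) -> tuple[float, float]:
    """Noiseless (dF_LGPL, dF_SO) for one position and resection condition."""
    f = forward_delta_F(truth, p_r).forces
    if condition == "intact":
        d_lgpl = f["INT"] + truth.c * f["NV1"] + f["NV2"]
        d_so = so_coupling * (f["INT"] + truth.c * f["NV1"])
    elif condition == "postI":
        d_lgpl = f["NV1"] + f["NV2"]
        d_so = so_coupling * f["NV1"]
    elif condition == "postII":
        d_lgpl = f["NV2"]
        d_so = 0.0
    else:
        raise StructuralError(f"unknown condition {condition!r}")
    return d_lgpl, d_so


def _noiseless_totals(
    spec: SyntheticSpec, p_r: float, condition: str, delta_lgpl: float | None = None
) -> dict[str, float]:
    """Total plateau force per channel; the proximal LG+PL tendon carries
    the constant baseline and the distal tendon the baseline minus dF."""
    if delta_lgpl is None:
        d_lgpl, d_so = condition_deltas(
            spec.truth, p_r, condition, spec.so_coupling
        )
    else:
        d_lgpl = delta_lgpl
        d_so = spec.so_coupling * d_lgpl
    return {
        "f_lgpl_prox": spec.baseline_lgpl_prox_N,
        "f_lgpl_dist": spec.baseline_lgpl_prox_N - d_lgpl,
        "f_so_dist": spec.baseline_so_N + d_so,
    }


def _passives(spec: SyntheticSpec) -> dict[str, float]:
    return {
        "f_lgpl_prox": spec.passive_lgpl_N,
        "f_lgpl_dist": spec.passive_lgpl_N,
        "f_so_dist": spec.passive_so_N,
    }


def generate_waveform(
    spec: SyntheticSpec,
    position_mm: float,
    condition: str = "intact",
    animal_id: str = "A01",
    rng: np.random.Generator | None = None,
) -> ForceWaveform:
    """Synthesise one tetanic contraction recording.

    The noiseless waveform is exactly flat over both 50-ms extraction
    windows, so isometric extraction returns the configured passive and
    total forces without bias.  ``rng`` adds per-sample Gaussian noise of
    SD ``spec.noise_sd_N``; omit it for a noiseless waveform.
    """
    n = int(round(spec.record_duration_s * spec.sampling_hz)) + 1
    t = np.arange(n) / spec.sampling_hz
    onset, offset = spec.tetanus_onset_s, spec.tetanus_onset_s + spec.tetanus_duration_s
    twitches = tuple(onset - lead for lead in spec.twitch_lead_s)
    passives = _passives(spec)
    totals = _noiseless_totals(spec, position_mm, condition)

    forces = {}
    for ch in CHANNELS:
        base, plateau = passives[ch], totals[ch]
        f = np.full(n, base)
        for tw in twitches:  # half-sine conditioning twitches
            m = (t >= tw) & (t < tw + spec.twitch_duration_s)
            f[m] += (
                0.25
                * (plateau - base)
                * np.sin(np.pi * (t[m] - tw) / spec.twitch_duration_s)
            )
        rise = 0.03  # s; fast tension development at tetanus onset
        m = (t >= onset) & (t < onset + rise)
        f[m] = base + (plateau - base) * (t[m] - onset) / rise
        f[(t >= onset + rise) & (t < offset)] = plateau
        m = t >= offset
        f[m] = base + (plateau - base) * np.exp(-(t[m] - offset) / 0.05)
        if rng is not None and spec.noise_sd_N > 0:
            f = f + rng.normal(0.0, spec.noise_sd_N, size=n)
        forces[ch] = f

    return ForceWaveform(
        time_s=t,
        forces_N=forces,
        stim_onset_s=onset,
        stim_offset_s=offset,
        twitch_times_s=twitches,
        position_mm=float(position_mm),
        condition=condition,
        group=spec.truth.group,
        animal_id=animal_id,
    )


def _build_table(
    spec: SyntheticSpec,
    animal_id: str,
    condition: str,
    rng: np.random.Generator,
    deltas: Sequence[float] | None = None,
    mode: str = "both",
) -> IsometricForceTable:
    positions = spec.protocol.positions
    rows = {}
    passives = _passives(spec)
    for i, p in enumerate(positions):
        totals = _noiseless_totals(
            spec, p, condition, None if deltas is None else deltas[i]
        )
        row = {}
        for ch in CHANNELS:
            row[f"passive_{ch}_N"] = passives[ch] + rng.normal(0.0, spec.noise_sd_N)
            row[f"total_{ch}_N"] = totals[ch] + rng.normal(0.0, spec.noise_sd_N)
        rows[p] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "position_mm"
    return IsometricForceTable(
        data=df,
        condition=condition,
        group=spec.truth.group,
        animal_id=animal_id,
        mode=mode,
    )


def generate_calibration_dataset(
    spec: SyntheticSpec, postII_all_animals: bool = False
) -> list[IsometricForceTable]:
    """Emulate the three-condition calibration experiment.

    Every animal is measured intact and after the post-I resection; the
    complete isolation (post II) is produced for the first animal only,
    matching its single-animal feasibility in situ, unless
    ``postII_all_animals`` is set.  Output order is deterministic given the
    spec and its seed.
    """
    rng = np.random.default_rng(spec.seed)
    tables: list[IsometricForceTable] = []
    for i in range(spec.n_animals):
        animal = f"{spec.truth.group or 'A'}{i + 1:02d}"
        for condition in ("intact", "postI"):
            tables.append(_build_table(spec, animal, condition, rng))
        if i == 0 or postII_all_animals:
            tables.append(_build_table(spec, animal, "postII", rng))
    return tables


def generate_testing_dataset(spec: SyntheticSpec) -> list[IsometricForceTable]:
    """Emulate the proximal-only repositioning (testing) experiment.

    The LG+PL force difference follows the segment-scaled forward model
    with the spec's ``r`` and a zero offset at the reference position, plus
    the same additive noise model as the calibration data.
    """
    if spec.r is None:
        raise StructuralError("testing dataset requires the scale factors r")
    rng = np.random.default_rng(spec.seed + 1)
    protocol = replace(spec.protocol, mode="proximal_only")
    spec = replace(spec, protocol=protocol)
    deltas = [
        forward_delta_F(spec.truth, p, int_segment_scale=spec.r).delta_f_lgpl
        for p in protocol.positions
    ]
    tables = []
    for i in range(spec.n_animals):
        animal = f"{spec.truth.group or 'A'}{i + 1:02d}"
        tables.append(
            _build_table(
                spec, animal, "intact", rng, deltas=deltas, mode="proximal_only"
            )
        )
    return tables
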