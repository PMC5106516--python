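"""Lumped-parameter model of epimuscular myofascial force transmission.

Two synergistic plantar-flexor actuators of the rat hindlimb — soleus (SO)
and the lateral gastrocnemius + plantaris complex (LG+PL) — exchange force
through connective-tissue pathways in addition to their tendons: the
intermuscular myofascial interface between the muscle bellies (``INT``) and
two extramuscular neurovascular tracts (``NV1``, between LG and SO, and
``NV2``, from the popliteal fossa to the gastrocnemii).  Each pathway is
represented as a piecewise-linear elastic element whose transmitted force
depends only on the relative position ``P_R`` (mm) between the two
muscle–tendon units, with ``P_R = 0`` the reference position (90° knee and
ankle angles) at which no net force is transmitted.

The net proximo-distal tendon force difference of LG+PL,

    dF_LGPL(P_R) = F_INT(P_R) + F_NV1(P_R) + F_NV2(P_R),

is the model's observable: a non-zero difference between the forces at the
two tendons of an isometric muscle is a direct measure of force leaving (or
entering) the muscle via non-myotendinous routes.  Pathway forces are
signed; in the default calibration the NV2 tract transmits opposite to INT
and NV1.

Internal units are newtons and millimetres throughout.  Stiffness values
are therefore N/mm internally; the mN/mm scale conventional in the
experimental literature appears only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .exceptions import (
    ExtrapolationError,
    InvalidInputError,
    ParameterError,
    StructuralError,
)

#: Pathway labels, in canonical order.
PATHWAYS = ("INT", "NV1", "NV2")

#: Resection conditions of the calibration experiment.
CONDITIONS = ("intact", "postI", "postII")

#: Connectivity groups: normal (NO) and tissue-integrating mesh (TI).
GROUPS = ("NO", "TI")

_ABS_TOL = 1e-12


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise InvalidInputError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class PositionProtocol:
    """Sequence of SO/LG+PL relative positions imposed in one experiment.

    Parameters
    ----------
    positions
        Relative positions ``P_R`` in mm, strictly increasing.  Exactly one
        entry must be 0 (the reference position).
    mode
        ``"both"`` — proximal and distal LG+PL tendons repositioned together
        (calibration protocol, muscle length constant); ``"proximal_only"``
        — only the proximal tendon repositioned (testing protocol).
    """

    positions: tuple[float, ...] = (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0)
    mode: str = "both"

    def __post_init__(self) -> None:
        pos = tuple(float(p) for p in self.positions)
        object.__setattr__(self, "positions", pos)
        if len(pos) < 2:
            raise StructuralError("protocol needs at least two positions")
        _require_finite("positions", *pos)
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise StructuralError("positions must be strictly increasing")
        if sum(1 for p in pos if p == 0.0) != 1:
            raise StructuralError("exactly one position must equal 0 (P_REF)")
        if self.mode not in ("both", "proximal_only"):
            raise ParameterError(f"unknown protocol mode {self.mode!r}")

    @property
    def reference_index(self) -> int:
        return self.positions.index(0.0)


@dataclass(frozen=True)
class PiecewiseStiffness:
    """Signed piecewise-linear stiffness of one force-transmission pathway.

    ``values[j]`` (N/mm) applies to the displacement-magnitude band
    ``[breakpoints[j], breakpoints[j+1]]`` mm.  The transmitted force is the
    signed cumulative integral of the stiffness from 0 to ``P_R``.  By
    default negative positions use odd symmetry, ``F(-P) = -F(P)``;
    supplying ``negative_values`` instead fits the negative side with its
    own segments (band ``j`` covering ``[-breakpoints[j+1], -breakpoints[j]]``).
    """

    pathway: str
    values: tuple[float, ...]
    breakpoints: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    negative_values: tuple[float, ...] | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise StructuralError(
                f"pathway must be one of {PATHWAYS}, got {self.pathway!r}"
            )
        vals = tuple(float(v) for v in self.values)
        bps = tuple(float(b) for b in self.breakpoints)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "breakpoints", bps)
        _require_finite("stiffness values", *vals)
        _require_finite("breakpoints", *bps)
        if bps[0] != 0.0:
            raise StructuralError("breakpoints must start at 0 mm")
        if any(b <= a for a, b in zip(bps, bps[1:])):
            raise StructuralError("breakpoints must be strictly increasing")
        if len(vals) != len(bps) - 1:
            raise StructuralError(
                f"{len(bps) - 1} segments require {len(bps) - 1} stiffness "
                f"values, got {len(vals)}"
            )
        if self.negative_values is not None:
            neg = tuple(float(v) for v in self.negative_values)
            _require_finite("negative-side stiffness values", *neg)
            if len(neg) != len(vals):
                raise StructuralError("negative side needs the same segment count")
            object.__setattr__(self, "negative_values", neg)

    @property
    def n_segments(self) -> int:
        return len(self.values)

    @property
    def span_mm(self) -> float:
        """Largest displacement magnitude covered by the segments."""
        return self.breakpoints[-1]

    @property
    def values_mN_per_mm(self) -> tuple[float, ...]:
        return tuple(1e3 * v for v in self.values)

    @property
    def symmetric(self) -> bool:
        return self.negative_values is None

    def force_at(
        self, p_r: float, segment_scale: Sequence[float] | None = None
    ) -> float:
        """Cumulative transmitted force (N) at relative position ``p_r`` mm.

        ``segment_scale`` multiplies each segment's stiffness (used for the
        proximal-only scale factor r); it must match the segment count.
        """
        _require_finite("P_R", p_r)
        if segment_scale is not None and len(segment_scale) != self.n_segments:
            raise StructuralError(
                f"segment_scale needs {self.n_segments} entries, "
                f"got {len(segment_scale)}"
            )
        x = abs(p_r)
        if x > self.span_mm + _ABS_TOL:
            raise ExtrapolationError(
                f"P_R = {p_r} mm outside the fitted span ±{self.span_mm} mm"
            )
        vals = self.values
        if p_r < 0 and self.negative_values is not None:
            vals = self.negative_values
        force = 0.0
        for j in range(self.n_segments):
            lo, hi = self.breakpoints[j], self.breakpoints[j + 1]
            overlap = min(x, hi) - lo
            if overlap <= 0.0:
                break
            k = vals[j]
            if segment_scale is not None:
                k *= segment_scale[j]
            force += k * overlap
        return -force if p_r < 0 else force


@dataclass(frozen=True)
class StiffnessSet:
    """The three pathway stiffnesses of one connectivity group, plus the
    dimensionless NV1 length-ratio parameter ``c``.

    ``c`` is the ratio of NV1 tract length before versus after resection of
    the intermuscular myofascial linkages; it discounts NV1's contribution
    in the intact condition relative to its post-resection behaviour.
    """

    pathways: Mapping[str, PiecewiseStiffness]
    group: str = ""
    c: float = 0.9

    def __post_init__(self) -> None:
        pw = dict(self.pathways)
        object.__setattr__(self, "pathways", pw)
        if set(pw) != set(PATHWAYS):
            raise StructuralError(
                f"stiffness set must contain exactly {PATHWAYS}, got {sorted(pw)}"
            )
        bps = {pw[name].breakpoints for name in PATHWAYS}
        if len(bps) != 1:
            raise StructuralError("all pathways must share breakpoints")
        if not (0.0 < self.c <= 1.0):
            raise ParameterError(f"c must lie in (0, 1], got {self.c}")

    @property
    def breakpoints(self) -> tuple[float, ...]:
        return self.pathways["INT"].breakpoints

    @property
    def n_segments(self) -> int:
        return self.pathways["INT"].n_segments

    @property
    def span_mm(self) -> float:
        return self.pathways["INT"].span_mm

    def force(
        self,
        pathway: str,
        p_r: float,
        segment_scale: Sequence[float] | None = None,
    ) -> float:
        return self.pathways[pathway].force_at(p_r, segment_scale)

    def with_group(self, group: str) -> "StiffnessSet":
        return replace(self, group=group)


@dataclass(frozen=True)
class ForwardForces:
    """Per-pathway cumulative forces and their signed sum at one position."""

    p_r: float
    forces: Mapping[str, float]

    @property
    def delta_f_lgpl(self) -> float:
        return sum(self.forces.values())


def forward_delta_F(
    stiffness: StiffnessSet,
    p_r: float,
    int_segment_scale: Sequence[float] | None = None,
) -> ForwardForces:
    """Forward model: pathway forces and net dF_LGPL at position ``p_r``.

    Each pathway force is the signed cumulative integral of its segment
    stiffness from the reference position to ``p_r``; the net LG+PL
    proximo-distal force difference is their signed sum, and is exactly 0
    at the reference position.  ``int_segment_scale`` optionally scales the
    INT segments (the proximal-only factor r); NV1 and NV2 are never scaled.
    """
    forces = {
        "INT": stiffness.force("INT", p_r, int_segment_scale),
        "NV1": stiffness.force("NV1", p_r),
        "NV2": stiffness.force("NV2", p_r),
    }
    return ForwardForces(p_r=float(p_r), forces=forces)


@dataclass(frozen=True)
class NodeState:
    """Forces meeting at the two LG+PL tendon nodes of the lumped model.

    ``f_muscle`` lumps the contractile and parallel-elastic contributions
    (constant across conditions for isometric contractions at fixed
    muscle–tendon unit length).
    """

    f_prox: float
    f_dist: float
    f_muscle: float
    f_int: float = 0.0
    f_nv1: float = 0.0
    f_nv2: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(
            "node forces",
            self.f_prox,
            self.f_dist,
            self.f_muscle,
            self.f_int,
            self.f_nv1,
            self.f_nv2,
        )


def node_residuals(state: NodeState) -> tuple[float, float]:
    """Static force-balance residuals (N) at the proximal and distal nodes.

    Proximal node: ``F_prox - F_NV2 - F_muscle``; distal node:
    ``F_dist - F_muscle + F_INT + F_NV1``.  Both vanish in equilibrium, and
    their difference equals ``(F_prox - F_dist) - (F_NV2 + F_INT + F_NV1)``:
    the tendon force difference measures the net epimuscular force.
    """
    r1 = state.f_prox - state.f_nv2 - state.f_muscle
    r2 = state.f_dist - state.f_muscle + state.f_int + state.f_nv1
    return (r1, r2)


def equilibrium_state(forward: ForwardForces, f_muscle: float) -> NodeState:
    """Construct the unique node state in equilibrium with the forward-model
    pathway forces and a given lumped muscle force."""
    _require_finite("f_muscle", f_muscle)
    f = forward.forces
    return NodeState(
        f_prox=f_muscle + f["NV2"],
        f_dist=f_muscle - f["INT"] - f["NV1"],
        f_muscle=f_muscle,
        f_int=f["INT"],
        f_nv1=f["NV1"],
        f_nv2=f["NV2"],
    )


def interpolate_stiffness(
    no_set: StiffnessSet, ti_set: StiffnessSet, alpha: float
) -> StiffnessSet:
    """Linear interpolation between two connectivity conditions.

    ``alpha = 0`` returns the first set, ``alpha = 1`` the second; every
    segment stiffness and ``c`` interpolate linearly.  Intended for
    representing intermediate degrees of connective-tissue integration
    (e.g. partial scarring) between the normal and enhanced states.
    """
    _require_finite("alpha", alpha)
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError(f"alpha must lie in [0, 1], got {alpha}")
    if no_set.breakpoints != ti_set.breakpoints:
        raise StructuralError("stiffness sets must share breakpoints")
    mixed: dict[str, PiecewiseStiffness] = {}
    for name in PATHWAYS:
        a, b = no_set.pathways[name], ti_set.pathways[name]
        if (a.negative_values is None) != (b.negative_values is None):
            raise StructuralError(
                "stiffness sets must agree on negative-side handling"
            )
        vals = tuple(
            (1.0 - alpha) * va + alpha * vb for va, vb in zip(a.values, b.values)
        )
        neg = None
        if a.negative_values is not None and b.negative_values is not None:
            neg = tuple(
                (1.0 - alpha) * va + alpha * vb
                for va, vb in zip(a.negative_values, b.negative_values)
            )
        mixed[name] = PiecewiseStiffness(
            pathway=name,
            values=vals,
            breakpoints=a.breakpoints,
            negative_values=neg,
            group=None,
        )
    group = f"interp({no_set.group},{ti_set.group},{alpha:g})"
    c = (1.0 - alpha) * no_set.c + alpha * ti_set.c
    return StiffnessSet(pathways=mixed, group=group, c=c)


@dataclass(frozen=True)
class KneeAngleMap:
    """Affine map from proximal LG+PL displacement (mm) to knee angle (deg).

    The reference position corresponds to 90° knee and ankle angles; the
    slope depends on joint geometry (moment arm of the proximal tendon about
    the knee) and should be supplied from anatomical data.  The default
    slope of 10 deg/mm is an illustrative order of magnitude for the rat
    knee, not a measured value.
    """

    slope_deg_per_mm: float = 10.0
    intercept_deg: float = 90.0

    def __post_init__(self) -> None:
        _require_finite("map coefficients", self.slope_deg_per_mm, self.intercept_deg)


DEFAULT_KNEE_MAP = KneeAngleMap()


def position_to_knee_angle(
    p_r_prox: float, knee_map: KneeAngleMap = DEFAULT_KNEE_MAP
) -> float:
    """Knee angle (deg) corresponding to a proximal tendon displacement."""
    _require_finite("P_R_prox", p_r_prox)
    return knee_map.intercept_deg + knee_map.slope_deg_per_mm * p_r_prox
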