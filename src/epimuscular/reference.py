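"""Bundled calibration results for the two connectivity groups.

These fixtures hold the group-mean piecewise stiffnesses of the
intermuscular (INT) and neurovascular (NV1, NV2) pathways for normal (NO)
and tissue-integrating-mesh (TI) connectivity, together with the
proximal-only scale factors r.  They serve as ground truth for the
synthetic experiment generator and as a worked starting point for the
prediction tools.
"""

from __future__ import annotations

from importlib import resources

from .core import StiffnessSet
from .io import load_r_yaml, stiffness_from_dict

import yaml

#: Mean LG+PL proximal tendon force (N) at the reference position.
BASELINE_LGPL_PROX_N = 11.5

#: Mean SO distal tendon force (N) at the reference position.
BASELINE_SO_N = 1.3


def _read_data(name: str) -> str:
    return (resources.files("epimuscular") / "data" / name).read_text()


def control_stiffness() -> StiffnessSet:
    """Calibrated stiffness set for the normal-connectivity (NO) group."""
    return stiffness_from_dict(yaml.safe_load(_read_data("stiffness_control.yaml")))


def tissue_integration_stiffness() -> StiffnessSet:
    """Calibrated stiffness set for the tissue-integrating mesh (TI) group."""
    return stiffness_from_dict(
        yaml.safe_load(_read_data("stiffness_tissue_integration.yaml"))
    )


def scale_factor_r() -> tuple[float, ...]:
    """Per-segment proximal-only scale factors r."""
    import io as _io

    return load_r_yaml(_io.StringIO(_read_data("scale_factor_r.yaml")))


def stiffness_for_group(group: str) -> StiffnessSet:
    if group == "NO":
        return control_stiffness()
    if group == "TI":
        return tissue_integration_stiffness()
    raise ValueError(f"unknown group {group!r}; expected 'NO' or 'TI'")
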