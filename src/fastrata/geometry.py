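"""Tag-pair geometry for two-ended molecules.

Proteins such as talin and vinculin can be tagged at either terminus; the
vertical separation between the fitted N- and C-tag layers gives the
molecule's orientation (which end sits higher) and, together with an
assumed full molecular length L, an inclination angle

    theta = arcsin(|z_C - z_N| / L)

relative to the substrate plane.  L is deliberately a required user input:
no literature constant is shipped.  Differences between the fitted layer
centres of two different proteins (e.g. kank1 vs paxillin) use the same
machinery via :func:`layer_offset`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError
from .zprofile import ProteinSummary

#: |delta z| below which the two tags are called level (nm); motivated by
#: the sub-20 nm axial resolution class of the instrument
LEVEL_FLOOR_NM = 5.0


@dataclass
class TagGeometry:
    """N/C tag separation and derived orientation for one molecule."""

    protein: str
    z_n: float  # fitted Z_centre of the N-terminal tag, nm
    z_c: float  # fitted Z_centre of the C-terminal tag, nm
    delta_z: float  # z_c - z_n, signed nm
    orientation: str  # "C-above-N" | "N-above-C" | "level"
    length_nm: float | None = None
    theta_deg: float | None = None


def _single_centre(summary: ProteinSummary) -> float:
    if summary.model_order != 1:
        raise ValueError(
            f"{summary.protein}: tag geometry requires single-component summaries"
        )
    return summary.components[0].z_centre_mean


def tag_separation(summary_n: ProteinSummary, summary_c: ProteinSummary) -> float:
    """Signed vertical separation z_C - z_N (positive = C-terminus higher),
    using the mean Z_centre of each single-component summary."""
    return _single_centre(summary_c) - _single_centre(summary_n)


def orientation_verdict(delta_z: float, level_floor_nm: float = LEVEL_FLOOR_NM) -> str:
    if abs(delta_z) <= level_floor_nm:
        return "level"
    return "C-above-N" if delta_z > 0 else "N-above-C"


def inclination_angle(delta_z: float, length_nm: float) -> float:
    """Inclination angle theta = arcsin(|delta_z| / L) in degrees."""
    if length_nm <= 0:
        raise ValueError("length must be positive")
    if abs(delta_z) > length_nm:
        raise GeometryError(
            f"|delta_z| = {abs(delta_z):.1f} nm exceeds molecular length {length_nm:.1f} nm"
        )
    return float(np.degrees(np.arcsin(abs(delta_z) / length_nm)))


def tag_geometry(
    protein: str,
    summary_n: ProteinSummary,
    summary_c: ProteinSummary,
    length_nm: float | None = None,
    level_floor_nm: float = LEVEL_FLOOR_NM,
) -> TagGeometry:
    """Full tag-pair geometry from two single-component summaries."""
    z_n = _single_centre(summary_n)
    z_c = _single_centre(summary_c)
    dz = z_c - z_n
    theta = inclination_angle(dz, length_nm) if length_nm is not None else None
    return TagGeometry(
        protein=protein, z_n=z_n, z_c=z_c, delta_z=dz,
        orientation=orientation_verdict(dz, level_floor_nm),
        length_nm=length_nm, theta_deg=theta,
    )


def layer_offset(summary_a: ProteinSummary, summary_b: ProteinSummary) -> float:
    """Z_centre(a) - Z_centre(b) between two proteins' layers, signed nm."""
    return _single_centre(summary_a) - _single_centre(summary_b)
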