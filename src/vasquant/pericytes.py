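"""Pericyte coverage of the vasculature.

Coverage is the ratio of the pericyte-channel area fraction to the
vessel-channel area fraction of the same field — a proxy for mural-cell
investment and vessel maturity.  Being a ratio of area fractions rather
than a geometric overlap, it can exceed 1 (e.g. with abundant off-vessel
marker signal); such values are reported as-is with a warning, never
clipped, because clipping would hide staining problems.

An optional restriction intersects the pericyte mask with a physical
dilation of the vessel mask before measuring, discarding marker signal far
from any vessel.  The unrestricted ratio is the default and the literal
definition of the metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from vasquant.errors import DegenerateInputError
from vasquant.metrics import area_fraction
from vasquant.preprocess import BinaryMask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverageResult:
    """Pericyte coverage of one field: area fractions and their ratio."""

    vessel_af: float
    pericyte_af: float
    coverage_ratio: float
    restricted: bool
    dilation_um: float


def _disk_offsets(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius_px**2


def pericyte_coverage(
    vessel_mask: BinaryMask,
    pericyte_mask: BinaryMask,
    restrict_to_vessel_um: float = 0.0,
) -> CoverageResult:
    """Coverage ratio = pericyte area fraction / vessel area fraction.

    With ``restrict_to_vessel_um > 0`` the pericyte foreground is first
    intersected with the vessel mask dilated by a disk of that physical
    radius (a suggested radius when enabling the restriction is 5 um, about
    one pericyte soma).

    Raises
    ------
    DegenerateInputError
        If the vessel mask is empty — the ratio is undefined.
    ValueError
        On shape or calibration mismatch between the two masks.
    """
    if vessel_mask.shape != pericyte_mask.shape:
        raise ValueError(
            f"mask shape mismatch: {vessel_mask.shape} vs {pericyte_mask.shape}"
        )
    if vessel_mask.pixel_size_um != pericyte_mask.pixel_size_um:
        raise ValueError("mask calibration mismatch")
    v_af = area_fraction(vessel_mask)
    if v_af == 0:
        raise DegenerateInputError("vessel area fraction is 0: coverage ratio undefined")
    restricted = restrict_to_vessel_um > 0
    peri = pericyte_mask.pixels
    if restricted:
        radius_px = restrict_to_vessel_um / vessel_mask.pixel_size_um
        halo = ndi.binary_dilation(vessel_mask.pixels, structure=_disk_offsets(radius_px))
        peri = peri & halo
    p_af = float(np.count_nonzero(peri)) / peri.size
    ratio = p_af / v_af
    if ratio > 1:
        logger.warning("pericyte coverage ratio %.3f exceeds 1 (reported unclipped)", ratio)
    return CoverageResult(
        vessel_af=v_af,
        pericyte_af=p_af,
        coverage_ratio=ratio,
        restricted=restricted,
        dilation_um=restrict_to_vessel_um if restricted else 0.0,
    )
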