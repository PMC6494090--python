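"""Axial-length correction of the lateral scale of macular OCT scans.

Spectral-domain OCT devices assume a fixed axial length when converting
scan angles to lateral millimetres, so the "6 mm" macular cube covers a
different physical extent in every eye.  The correction is linear: the
actual scan length is the nominal length times the ratio of the subject's
axial length to the device's assumed axial length (24.46 mm for the Cirrus
HD-OCT).  Thickness itself is an axial measurement and is unaffected; only
the lateral pixel coordinates rescale.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import ThicknessMap

#: Axial length (mm) assumed by the Cirrus HD-OCT when scaling scans laterally.
ASSUMED_AXIAL_MM = 24.46

#: Nominal lateral extent (mm) of the macular cube scan.
NOMINAL_EXTENT_MM = 6.0


@dataclass(frozen=True)
class ScaleResult:
    """Outcome of the axial-length correction for one eye."""

    actual_extent_mm: float
    scale_factor: float


def actual_scan_length(
    axial_mm: float,
    nominal_mm: float = NOMINAL_EXTENT_MM,
    assumed_axial_mm: float = ASSUMED_AXIAL_MM,
) -> float:
    """Physical lateral extent (mm) of a scan acquired in an eye of given axial length.

    Raises
    ------
    ValueError
        If ``axial_mm`` lies outside [15, 35] mm, which almost always
        signals a units mistake (e.g. metres or dioptres).
    """
    if not 15.0 <= axial_mm <= 35.0:
        raise ValueError(
            f"axial length {axial_mm} mm outside plausible [15, 35] mm range; "
            "check units"
        )
    return nominal_mm * axial_mm / assumed_axial_mm


def scale_result(
    axial_mm: float,
    nominal_mm: float = NOMINAL_EXTENT_MM,
    assumed_axial_mm: float = ASSUMED_AXIAL_MM,
) -> ScaleResult:
    factor = axial_mm / assumed_axial_mm
    return ScaleResult(
        actual_extent_mm=actual_scan_length(axial_mm, nominal_mm, assumed_axial_mm),
        scale_factor=factor,
    )


def apply_scale(
    tmap: ThicknessMap,
    axial_mm: float | None,
    assumed_axial_mm: float = ASSUMED_AXIAL_MM,
) -> ThicknessMap:
    """Return a copy of ``tmap`` whose pixel pitch reflects the true lateral scale.

    Pixel values are untouched; only the physical (row, col) pitch is
    multiplied by axial / assumed ratio, so all downstream distances
    (sector radii, pit profiles) use corrected coordinates.
    """
    if axial_mm is None:
        raise ValueError(
            "axial length absent: pass an axial length or skip the correction "
            "explicitly by not calling apply_scale"
        )
    res = scale_result(axial_mm, tmap.nominal_extent_mm, assumed_axial_mm)
    rp, cp = tmap.pixel_pitch_mm
    return tmap.with_pitch((rp * res.scale_factor, cp * res.scale_factor))
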