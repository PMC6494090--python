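"""Fovea-centred ETDRS sectorisation of macular thickness maps.

The ETDRS layout divides the macula into a central 1 mm disc and two
rings (1-3 mm "inner", 3-6 mm "outer"), each ring split into superior,
inferior, nasal and temporal quadrants on the ±45° diagonals.  Sectors are
computed around the detected foveal centre — not the scan centre — using
the axial-length-corrected pixel pitch, so a short eye's corrected scan
covers less than the nominal 6 mm and outer sectors may be truncated;
the per-sector ``coverage`` fraction reports how much of each sector's
area the scan actually sampled.

Conventions (documented because devices differ): row 0 of the en-face
matrix is superior; angles are measured anticlockwise from the positive
column axis with "up" = superior; quadrant intervals are half-open,
[45°, 135°) superior, [225°, 315°) inferior, [135°, 225°) on the left
column side, [315°, 45°) on the right.  For OD the nasal quadrant lies on
the left column side by default (``od_nasal_side``), mirrored for OS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ThicknessMap

SECTORS = (
    "center_1mm",
    "inner_superior",
    "inner_inferior",
    "inner_nasal",
    "inner_temporal",
    "outer_superior",
    "outer_inferior",
    "outer_nasal",
    "outer_temporal",
)

#: ETDRS ring radii in mm: centre disc, inner ring, outer ring.
R_CENTER, R_INNER, R_OUTER = 0.5, 1.5, 3.0

_SECTOR_AREAS_MM2 = {
    "center_1mm": np.pi * R_CENTER**2,
    **{
        f"inner_{q}": np.pi * (R_INNER**2 - R_CENTER**2) / 4
        for q in ("superior", "inferior", "nasal", "temporal")
    },
    **{
        f"outer_{q}": np.pi * (R_OUTER**2 - R_INNER**2) / 4
        for q in ("superior", "inferior", "nasal", "temporal")
    },
}


class FoveaNotLocalizedError(RuntimeError):
    """The smoothed thickness minimum was degenerate or on the search boundary."""


@dataclass
class EtdrsGrid:
    """Mean thickness (µm) of the nine ETDRS sectors plus sampling coverage."""

    sector_means: dict[str, float]
    coverage: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def __getattr__(self, name: str) -> float:
        means = object.__getattribute__(self, "sector_means")
        if name in means:
            return means[name]
        raise AttributeError(name)

    def as_dict(self) -> dict[str, float]:
        return dict(self.sector_means)


def locate_fovea(
    tmap: ThicknessMap, smooth_fwhm_mm: float = 0.25
) -> tuple[float, float]:
    """Detect the foveal centre as the minimum of a smoothed thickness map.

    The map is Gaussian-smoothed (FWHM ``smooth_fwhm_mm``), the discrete
    minimum is sought inside the central half of the field, and a
    separable quadratic fit to the 3×3 neighbourhood refines the position
    to sub-pixel accuracy.

    Returns continuous (row, col) coordinates.

    Raises
    ------
    FoveaNotLocalizedError
        If the smoothed field has no unique interior minimum (flat map) or
        the minimum sits on the boundary of the central search region.
    """
    nrow, ncol = tmap.shape
    if nrow < 32 or ncol < 32:
        raise ValueError("map too small to localise the fovea (need ≥ 32×32)")
    sigma_px = (
        smooth_fwhm_mm / 2.3548 / tmap.pixel_pitch_mm[0],
        smooth_fwhm_mm / 2.3548 / tmap.pixel_pitch_mm[1],
    )
    values = np.where(np.isfinite(tmap.values), tmap.values, np.nanmedian(tmap.values))
    smoothed = ndimage.gaussian_filter(values, sigma_px, mode="nearest")

    r0, r1 = nrow // 4, nrow - nrow // 4
    c0, c1 = ncol // 4, ncol - ncol // 4
    region = smoothed[r0:r1, c0:c1]
    if np.ptp(region) < 1e-9:
        raise FoveaNotLocalizedError("smoothed field is flat; no unique minimum")
    ir, ic = np.unravel_index(np.argmin(region), region.shape)
    if ir in (0, region.shape[0] - 1) or ic in (0, region.shape[1] - 1):
        raise FoveaNotLocalizedError(
            "fovea not localized: minimum on central search-region boundary"
        )
    ir, ic = ir + r0, ic + c0

    def _refine(fm1: float, f0: float, fp1: float) -> float:
        denom = fm1 - 2 * f0 + fp1
        return 0.0 if denom <= 0 else 0.5 * (fm1 - fp1) / denom

    dr = _refine(smoothed[ir - 1, ic], smoothed[ir, ic], smoothed[ir + 1, ic])
    dc = _refine(smoothed[ir, ic - 1], smoothed[ir, ic], smoothed[ir, ic + 1])
    return float(ir + dr), float(ic + dc)


def sector_labels(
    shape: tuple[int, int],
    fovea_rc: tuple[float, float],
    pixel_pitch_mm: tuple[float, float],
    laterality: str,
    od_nasal_side: str = "left",
) -> np.ndarray:
    """Assign every pixel its ETDRS sector name ('' outside the 3 mm radius).

    Pixels are assigned by the physical distance of their centre from the
    fovea, half-open on ring boundaries (centre d ≤ 0.5; inner 0.5 < d ≤ 1.5;
    outer 1.5 < d ≤ 3.0 mm) and on the diagonal quadrant boundaries.
    """
    if od_nasal_side not in ("left", "right"):
        raise ValueError("od_nasal_side must be 'left' or 'right'")
    nrow, ncol = shape
    fr, fc = fovea_rc
    rp, cp = pixel_pitch_mm
    rows = (np.arange(nrow)[:, None] - fr) * rp
    cols = (np.arange(ncol)[None, :] - fc) * cp
    d = np.hypot(rows, cols)
    # up = superior (row 0 superior), right = +col
    theta = np.degrees(np.arctan2(-rows, np.broadcast_to(cols, d.shape))) % 360.0

    nasal_left = (laterality == "OD") == (od_nasal_side == "left")
    left_q, right_q = ("nasal", "temporal") if nasal_left else ("temporal", "nasal")

    quad = np.full(d.shape, right_q, dtype=object)  # [315, 45)
    quad[(theta >= 45.0) & (theta < 135.0)] = "superior"
    quad[(theta >= 135.0) & (theta < 225.0)] = left_q
    quad[(theta >= 225.0) & (theta < 315.0)] = "inferior"

    labels = np.full(d.shape, "", dtype=object)
    labels[d <= R_CENTER] = "center_1mm"
    inner = (d > R_CENTER) & (d <= R_INNER)
    outer = (d > R_INNER) & (d <= R_OUTER)
    labels[inner] = np.char.add("inner_", quad[inner].astype(str))
    labels[outer] = np.char.add("outer_", quad[outer].astype(str))
    return labels


def compute_etdrs(
    tmap: ThicknessMap,
    fovea_rc: tuple[float, float],
    od_nasal_side: str = "left",
    coverage_floor: float = 0.25,
) -> EtdrsGrid:
    """Mean thickness of each ETDRS sector around ``fovea_rc``.

    Requires the axial-length-corrected pixel pitch to be set on the map.
    Partial sectors (scan edge inside the 6 mm circle) are averaged over
    the available pixels; ``coverage`` is the sampled fraction of each
    sector's geometric area (pixel count × pixel area / sector area).
    Sectors with coverage below ``coverage_floor`` get a recorded warning;
    sectors with no pixels at all are flagged missing (NaN).
    """
    nrow, ncol = tmap.shape
    fr, fc = fovea_rc
    if not (0 <= fr <= nrow - 1 and 0 <= fc <= ncol - 1):
        raise ValueError(f"fovea {fovea_rc} outside map bounds")
    labels = sector_labels(
        tmap.shape, fovea_rc, tmap.pixel_pitch_mm, tmap.laterality, od_nasal_side
    )
    px_area = tmap.pixel_pitch_mm[0] * tmap.pixel_pitch_mm[1]
    means: dict[str, float] = {}
    coverage: dict[str, float] = {}
    warnings: list[str] = []
    for sector in SECTORS:
        vals = tmap.values[labels == sector]
        vals = vals[np.isfinite(vals)]
        cov = min(1.0, vals.size * px_area / _SECTOR_AREAS_MM2[sector])
        coverage[sector] = cov
        if vals.size == 0:
            means[sector] = float("nan")
            warnings.append(f"sector {sector}: no contributing pixels")
            continue
        means[sector] = float(vals.mean())
        if cov < coverage_floor:
            warnings.append(f"sector {sector}: coverage {cov:.2f} below {coverage_floor}")
    return EtdrsGrid(sector_means=means, coverage=coverage, warnings=warnings)
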