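"""Synthetic macular cohorts with known ground truth.

The study data this package analyses — paired-eye OCT thickness maps from
Parkinson's patients and controls — are not publicly deposited, so every
pipeline stage is exercised against simulated cohorts in which the truth
is known: each eye's thickness surface is an exact difference-of-Gaussians
(DoG) pit, axial lengths are drawn from a truncated normal, fellow eyes
are correlated copies, and disease / sex effects are planted as additive
regional offsets.

Two deliberate realism choices matter downstream:

* **Mis-scaled metadata.** Each map is sampled on the TRUE physical grid
  implied by the eye's axial length (extent 6·AL/24.46 mm) but its sidecar
  records the nominal 6 mm extent — exactly the error a fixed-optics OCT
  device makes.  The axial-length correction must be applied to recover
  physical coordinates, so the correction is exercised end to end.
* **Correlated fellow eyes.** OS pit parameters are the OD parameters plus
  small Gaussian jitter, so interocular agreement statistics have a
  realistic near-zero bias to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .etdrs import SECTORS, sector_labels
from .io import Cohort, SubjectRecord, ThicknessMap
from .scaling import ASSUMED_AXIAL_MM, NOMINAL_EXTENT_MM

#: Population distribution of pit parameters (mean, sd); chosen so that the
#: derived metrics of a typical eye fall inside published adult ranges
#: (pit depth ≈ 0.11 mm, diameter ≈ 1.9 mm, max slope ≈ 12°, volume ≈ 0.074 mm³).
PIT_POPULATION = {
    "base_um": (276.0, 10.0),
    "a1_um": (48.0, 6.0),
    "s1_mm": (0.92, 0.06),
    "a2_um": (138.0, 10.0),
    "s2_mm": (0.37, 0.025),
}

#: SD (mm) of the random fovea decentration from the scan centre (fixation error).
FOVEA_OFFSET_SD_MM = 0.1


@dataclass(frozen=True)
class PitParams:
    """Difference-of-Gaussians foveal surface parameters.

    thickness(r) = base + a1·exp(−r²/2s1²) − a2·exp(−r²/2s2²), r in mm,
    thickness in µm.  The broad positive Gaussian (a1, s1) forms the
    parafoveal rim and peripheral decline; the narrow negative Gaussian
    (a2, s2) carves the pit.
    """

    base_um: float
    a1_um: float
    s1_mm: float
    a2_um: float
    s2_mm: float

    def __post_init__(self) -> None:
        if not (self.s1_mm > self.s2_mm > 0):
            raise ValueError(f"need s1 > s2 > 0, got s1={self.s1_mm}, s2={self.s2_mm}")
        if not (self.a1_um >= 0 and self.a2_um >= 0):
            raise ValueError("Gaussian amplitudes must be non-negative")
        if not self.base_um + self.a1_um - self.a2_um > 0:
            raise ValueError("central thickness base + a1 - a2 must be positive")

    def as_dict(self) -> dict[str, float]:
        return {
            "base_um": self.base_um,
            "a1_um": self.a1_um,
            "s1_mm": self.s1_mm,
            "a2_um": self.a2_um,
            "s2_mm": self.s2_mm,
        }


def pit_surface(params: PitParams, r_mm) -> np.ndarray | float:
    """Evaluate the DoG thickness surface (µm) at radius ``r_mm`` (mm)."""
    r2 = np.square(r_mm)
    return (
        params.base_um
        + params.a1_um * np.exp(-r2 / (2 * params.s1_mm**2))
        - params.a2_um * np.exp(-r2 / (2 * params.s2_mm**2))
    )


@dataclass
class SimConfig:
    """Study-design parameters of a simulated cohort.

    Defaults reproduce the reference study's design: 33 Parkinson's and
    40 control subjects, paired eyes, axial lengths truncated to the
    observed [21, 28] mm range, disease and sex effects as small additive
    thinning offsets, and a few micrometres of per-pixel measurement noise.
    """

    #: ``regional_sd_um`` is the SD of each subject's idiosyncratic per-sector
    #: thickness deviation (quadrant asymmetries of real retinas); without it
    #: sector contrasts would be deterministic functions of the planted
    #: offsets and any group effect would be trivially separable.
    n_pd: int = 33
    n_hc: int = 40
    grid_dim: int = 128
    axial_mean_mm: float = 23.9
    axial_sd_mm: float = 1.2
    interocular_sd_um: float = 2.0
    group_offsets_um: dict[str, float] = field(
        default_factory=lambda: {s: -5.0 for s in SECTORS}
    )
    sex_offset_um: float = -8.0
    regional_sd_um: float = 4.0
    noise_sd_um: float = 2.0
    female_fraction: tuple[float, float] = (0.39, 0.70)  # (PD, HC)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pd < 1 or self.n_hc < 1:
            raise ValueError("group sizes must be ≥ 1")
        if min(self.axial_sd_mm, self.interocular_sd_um, self.noise_sd_um) < 0:
            raise ValueError("standard deviations must be ≥ 0")
        unknown = set(self.group_offsets_um) - set(SECTORS)
        if unknown:
            raise ValueError(f"unknown sectors in group_offsets_um: {sorted(unknown)}")


def _truncnorm_axial(mean: float, sd: float, rng: np.random.Generator) -> float:
    # observed axial range [21.40, 27.89] mm rounded outward
    lo, hi = 21.0, 28.0
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_eye(
    params: PitParams,
    axial_mm: float,
    grid_dim: int,
    noise_sd_um: float,
    fovea_offset_mm: tuple[float, float] = (0.0, 0.0),
    laterality: str = "OD",
    rng: Optional[np.random.Generator] = None,
    sector_offsets_um: Optional[dict[str, float]] = None,
) -> ThicknessMap:
    """Sample one eye's thickness map from the DoG forward model.

    The grid is sampled at the TRUE pixel pitch implied by the axial
    length (6·AL/24.46 mm over grid_dim − 1 steps) while the map's
    metadata records the nominal 6 mm extent — the mis-scaling the
    axial-length correction exists to undo.  ``sector_offsets_um`` are
    additive regional thickness offsets (disease effects) applied per
    ETDRS sector; pixels beyond the outer ring take their quadrant's
    outer-ring offset so the periphery has no ring discontinuity.
    """
    if grid_dim < 32:
        raise ValueError("grid_dim must be ≥ 32")
    rng = np.random.default_rng() if rng is None else rng
    true_extent = NOMINAL_EXTENT_MM * axial_mm / ASSUMED_AXIAL_MM
    pitch = true_extent / (grid_dim - 1)
    center = (grid_dim - 1) / 2.0
    f_r = center + fovea_offset_mm[0] / pitch
    f_c = center + fovea_offset_mm[1] / pitch
    if not (grid_dim / 3 <= f_r <= 2 * grid_dim / 3 and grid_dim / 3 <= f_c <= 2 * grid_dim / 3):
        raise ValueError(
            f"fovea offset {fovea_offset_mm} mm places fovea outside the "
            "central third of the grid"
        )
    rows = (np.arange(grid_dim)[:, None] - f_r) * pitch
    cols = (np.arange(grid_dim)[None, :] - f_c) * pitch
    r = np.hypot(rows, cols)
    values = pit_surface(params, r)
    if sector_offsets_um:
        labels = sector_labels(
            (grid_dim, grid_dim), (f_r, f_c), (pitch, pitch), laterality
        )
        quad = np.degrees(np.arctan2(-rows, np.broadcast_to(cols, r.shape))) % 360.0
        for sector, off in sector_offsets_um.items():
            if off:
                values = values + off * (labels == sector)
        # extend outer-ring offsets beyond 3 mm
        beyond = labels == ""
        if beyond.any():
            nasal_left = laterality == "OD"
            lq, rq = ("nasal", "temporal") if nasal_left else ("temporal", "nasal")
            for (lo, hi), q in [
                ((45.0, 135.0), "superior"),
                ((135.0, 225.0), lq),
                ((225.0, 315.0), "inferior"),
            ]:
                off = sector_offsets_um.get(f"outer_{q}", 0.0)
                if off:
                    values = values + off * (beyond & (quad >= lo) & (quad < hi))
            off = sector_offsets_um.get(f"outer_{rq}", 0.0)
            if off:
                values = values + off * (beyond & ((quad >= 315.0) | (quad < 45.0)))
    if noise_sd_um > 0:
        values = values + rng.normal(0.0, noise_sd_um, values.shape)
    return ThicknessMap(
        values=values,
        laterality=laterality,
        nominal_extent_mm=NOMINAL_EXTENT_MM,
        fovea_rc=(f_r, f_c),
        quality=10.0,
    )


def _draw_pit_params(rng: np.random.Generator) -> PitParams:
    for _ in range(100):
        draw = {k: rng.normal(m, s) for k, (m, s) in PIT_POPULATION.items()}
        try:
            return PitParams(**draw)
        except ValueError:
            continue
    raise RuntimeError("could not draw valid pit parameters")


def _jitter(params: PitParams, sd_um: float, rng: np.random.Generator) -> PitParams:
    if sd_um == 0:
        return params
    return PitParams(
        base_um=params.base_um + rng.normal(0, sd_um),
        a1_um=max(0.0, params.a1_um + rng.normal(0, sd_um)),
        s1_mm=params.s1_mm * (1 + rng.normal(0, sd_um / 1000.0)),
        a2_um=max(0.0, params.a2_um + rng.normal(0, sd_um)),
        s2_mm=params.s2_mm * (1 + rng.normal(0, sd_um / 1000.0)),
    )


def generate_cohort(config: SimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a full paired-eye cohort.

    Returns the :class:`~macula.io.Cohort` plus a ground-truth table with
    one row per eye: the exact per-eye pit parameters (after group/sex
    offsets to the baseline), axial length, fovea decentration and the
    per-sector offsets applied.  Everything is reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectRecord] = []
    maps: dict[tuple[str, str], ThicknessMap] = {}
    truth_rows: list[dict] = []

    for group, n, female_frac in (
        ("PD", config.n_pd, config.female_fraction[0]),
        ("HC", config.n_hc, config.female_fraction[1]),
    ):
        n_female = int(round(n * female_frac))
        sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
        rng.shuffle(sexes)
        for i in range(n):
            sid = f"{group}_{i + 1:03d}"
            sex = str(sexes[i])
            age = float(np.clip(rng.normal(63.0, 10.0), 35, 90))
            axial = _truncnorm_axial(config.axial_mean_mm, config.axial_sd_mm, rng)
            base_params = _draw_pit_params(rng)
            if sex == "F" and config.sex_offset_um:
                base_params = replace(
                    base_params, base_um=base_params.base_um + config.sex_offset_um
                )
            regional = {
                s: float(rng.normal(0.0, config.regional_sd_um)) if config.regional_sd_um else 0.0
                for s in SECTORS
            }
            group_part = config.group_offsets_um if group == "PD" else {}
            offsets = {
                s: regional[s] + group_part.get(s, 0.0)
                for s in SECTORS
                if regional[s] or group_part.get(s, 0.0)
            }
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    sex=sex,
                    age_years=round(age, 1),
                    axial_length_od_mm=round(axial, 2),
                    axial_length_os_mm=round(axial, 2),
                    age_at_diagnosis=(
                        round(age - float(rng.uniform(1, 8)), 1) if group == "PD" else None
                    ),
                )
            )
            od_params = base_params
            os_params = _jitter(base_params, config.interocular_sd_um, rng)
            # fixation bias is modelled per subject and mirrored for the left
            # eye, so noiseless fellow eyes are exact mirror images and
            # interocular metric differences vanish when jitter is zero
            base_offset = np.clip(rng.normal(0, FOVEA_OFFSET_SD_MM, 2), -0.3, 0.3)
            for lat, params in (("OD", od_params), ("OS", os_params)):
                offset_rc = (
                    float(base_offset[0]),
                    float(base_offset[1] if lat == "OD" else -base_offset[1]),
                )
                maps[(sid, lat)] = generate_eye(
                    params,
                    axial_mm=round(axial, 2),
                    grid_dim=config.grid_dim,
                    noise_sd_um=config.noise_sd_um,
                    fovea_offset_mm=offset_rc,
                    laterality=lat,
                    rng=rng,
                    sector_offsets_um=offsets,
                )
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "sex": sex,
                        "laterality": lat,
                        "axial_mm": round(axial, 2),
                        **params.as_dict(),
                        "fovea_offset_row_mm": offset_rc[0],
                        "fovea_offset_col_mm": offset_rc[1],
                        **{f"offset_{s}": offsets.get(s, 0.0) for s in SECTORS},
                    }
                )
    truth = pd.DataFrame(truth_rows)
    return Cohort(subjects=subjects, maps=maps), truth
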