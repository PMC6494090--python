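"""End-to-end per-eye feature extraction.

Given a cohort of thickness maps with axial lengths, this runs the full
chain — axial-length scale correction, fovea localisation, ETDRS
sectorisation, and (optionally) the DoG pit fit — and assembles the flat
per-eye table that the interocular and logistic analyses consume.
"""

from __future__ import annotations

import logging

import pandas as pd

from .etdrs import SECTORS, compute_etdrs, locate_fovea
from .fovea import fit_dog, radial_profile
from .io import Cohort
from .model import fit_logistic  # noqa: F401  (re-exported convenience)
from .scaling import apply_scale

logger = logging.getLogger(__name__)


def eye_table(
    cohort: Cohort,
    fit_pit: bool = True,
    correct_axial: bool = True,
    dog_seed: int = 0,
) -> pd.DataFrame:
    """One row per eye: covariates, 9 ETDRS sector means, foveal metrics.

    ``sex_female`` is coded 1 = female and ``outcome`` 1 = PD.  Eyes
    without an axial length are processed uncorrected (logged) when
    ``correct_axial`` is set; pit metrics of non-converged fits are NaN.
    """
    rows = []
    for (sid, lat), tmap in cohort.maps.items():
        rec = cohort.subject(sid)
        if correct_axial:
            axial = rec.axial_length(lat)
            if axial is None:
                logger.warning("eye (%s, %s): axial length absent, not corrected", sid, lat)
            else:
                tmap = apply_scale(tmap, axial)
        fovea = locate_fovea(tmap)
        grid = compute_etdrs(tmap, fovea)
        row = {
            "subject_id": sid,
            "laterality": lat,
            "outcome": 1 if rec.group == "PD" else 0,
            "sex_female": 1 if rec.sex == "F" else 0,
            "age_years": rec.age_years,
            **{s: grid.sector_means[s] for s in SECTORS},
            "min_coverage": min(grid.coverage.values()),
        }
        if fit_pit:
            fit = fit_dog(radial_profile(tmap, fovea), seed=dog_seed)
            if fit.converged:
                m = fit.metrics()
                row.update(m.as_dict())
                row["no_pit"] = m.no_pit
            else:
                row.update(
                    {"depth_mm": float("nan"), "diameter_mm": float("nan"),
                     "slope_deg": float("nan"), "volume_mm3": float("nan"),
                     "no_pit": True}
                )
            row["converged"] = fit.converged
        rows.append(row)
    return pd.DataFrame(rows)
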