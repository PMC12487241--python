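"""Plate-level quality control: Z'-factor and coefficient of variation.

Every plate is gated on the screening-window coefficient
Z' = 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg| (> 0.5) and on the
negative-control CV = 100 * sd/mean (< 10%) before any hit calling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .outliers import grubbs_filter
from .plates import ROLE_NEGATIVE, ROLE_POSITIVE

#: Default gates, strict as printed: Z' > 0.5 and CV < 10%.
DEFAULT_Z_MIN = 0.5
DEFAULT_CV_MAX = 10.0


class UndefinedWindowError(ValueError):
    """Z' is undefined when the control means coincide."""


@dataclass
class PlateQC:
    """QC summary for one plate."""

    plate_id: str
    z_prime: float
    cv_percent: float
    n_pos: int
    n_neg: int
    passed: bool = False
    n_pos_removed: int = 0
    n_neg_removed: int = 0


def z_prime(positive_areas, negative_areas) -> float:
    """Screening-window coefficient between positive and negative controls.

    Uses sample (n-1) standard deviations. Requires >= 2 values per group
    and distinct group means.
    """
    pos = np.asarray(positive_areas, dtype=float)
    neg = np.asarray(negative_areas, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >= 2 control values per group")
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        raise UndefinedWindowError("control means coincide; Z' undefined")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / abs(mu_p - mu_n))


def plate_cv(negative_areas) -> float:
    """Coefficient of variation of the negative controls, in percent."""
    neg = np.asarray(negative_areas, dtype=float)
    if neg.size < 2:
        raise ValueError("need >= 2 values")
    mean = neg.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * neg.std(ddof=1) / mean)


def gate_plate(qc: PlateQC, z_min: float = DEFAULT_Z_MIN, cv_max: float = DEFAULT_CV_MAX) -> PlateQC:
    """Return a copy of ``qc`` with the pass flag set (strict comparisons)."""
    return replace(qc, passed=bool(qc.z_prime > z_min and qc.cv_percent < cv_max))


def qc_plates(
    records: pd.DataFrame,
    z_min: float = DEFAULT_Z_MIN,
    cv_max: float = DEFAULT_CV_MAX,
    grubbs_alpha: float = 0.05,
) -> list[PlateQC]:
    """Compute gated QC for every plate in a well-record table.

    ``records`` needs columns plate_id, role, area_um2. Control populations
    are Grubbs-filtered (per plate, per role) before the statistics, so a
    single segmentation failure does not sink a plate.
    """
    out: list[PlateQC] = []
    for plate_id, grp in records.groupby("plate_id", sort=True):
        pos = grp.loc[grp["role"] == ROLE_POSITIVE, "area_um2"].to_numpy(float)
        neg = grp.loc[grp["role"] == ROLE_NEGATIVE, "area_um2"].to_numpy(float)
        pos_rep = grubbs_filter(pos, alpha=grubbs_alpha)
        neg_rep = grubbs_filter(neg, alpha=grubbs_alpha)
        pos_c, neg_c = pos_rep.cleaned, neg_rep.cleaned
        qc = PlateQC(
            plate_id=str(plate_id),
            z_prime=z_prime(pos_c, neg_c),
            cv_percent=plate_cv(neg_c),
            n_pos=int(pos_c.size),
            n_neg=int(neg_c.size),
            n_pos_removed=pos_rep.n_removed,
            n_neg_removed=neg_rep.n_removed,
        )
        out.append(gate_plate(qc, z_min=z_min, cv_max=cv_max))
    return out


def qc_table(qcs: list[PlateQC]) -> pd.DataFrame:
    """QC report as a table (plate_id, z_prime, cv_percent, n_pos, n_neg, passed)."""
    return pd.DataFrame(
        {
            "plate_id": [q.plate_id for q in qcs],
            "z_prime": [q.z_prime for q in qcs],
            "cv_percent": [q.cv_percent for q in qcs],
            "n_pos": [q.n_pos for q in qcs],
            "n_neg": [q.n_neg for q in qcs],
            "passed": [q.passed for q in qcs],
        }
    )
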