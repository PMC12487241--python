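"""Two-stage dual-replicate hit calling on raw MIP areas.

Per plate, the DMSO wells (after iterative Grubbs filtering) define both
the raw-area cutoff  C = mean_DMSO - 3 * sd_DMSO  and the normalisation
denominator. A compound passes stage 1 if its raw area falls below the
cutoff on *every* replicate plate; stage-1 survivors pass stage 2 if their
residual area (percent of plate DMSO mean) is below 50% on every replicate.
Stage-2 survivors are flagged for review (the screen's manual visual
inspection); review acceptance defaults to yes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .outliers import grubbs_filter
from .plates import ROLE_COMPOUND, ROLE_NEGATIVE
from .qc import PlateQC

#: Stage-2 gate: residual area must be below this percent on all replicates.
DEFAULT_RESIDUAL_MAX = 50.0


@dataclass
class PlateCutoff:
    """Plate-specific hit cutoff from the cleaned DMSO population."""

    plate_id: str
    dmso_mean: float
    dmso_sd: float
    cutoff: float  # mean - 3*sd; may legitimately be negative
    n_dmso: int
    n_removed: int = 0


def plate_cutoff(dmso_areas_clean, plate_id: str = "") -> PlateCutoff:
    """Cutoff = mean - 3 * sample SD of the (outlier-filtered) DMSO areas."""
    x = np.asarray(dmso_areas_clean, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 DMSO values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return PlateCutoff(plate_id=plate_id, dmso_mean=mean, dmso_sd=sd, cutoff=mean - 3.0 * sd, n_dmso=int(x.size))


def residual_percent(area, dmso_mean: float):
    """Residual MIP area as percent of the plate's DMSO mean."""
    if not dmso_mean > 0:
        raise ValueError("DMSO mean must be positive")
    return 100.0 * np.asarray(area, dtype=float) / dmso_mean


class HitCaller(BaseEstimator):
    """Screen-wide hit caller.

    Parameters
    ----------
    grubbs_alpha : float
        Significance level of the per-plate DMSO outlier filter.
    residual_max : float
        Stage-2 residual-percent gate (strictly below, on all replicates).
    n_replicates_expected : int
        Replicate wells expected per compound x concentration; groups with
        fewer get a ``missing_data`` flag but are still reported.

    After ``fit(records, qc=...)``:

    decisions_ : DataFrame
        One row per compound x concentration with areas, cutoffs,
        residuals, stage flags and the final call.
    cutoffs_ : dict[str, PlateCutoff]
    funnel_ : dict
        Stage counts (tested -> stage1 -> stage2 -> final hits).
    """

    def __init__(
        self,
        grubbs_alpha: float = 0.05,
        residual_max: float = DEFAULT_RESIDUAL_MAX,
        n_replicates_expected: int = 2,
    ):
        self.grubbs_alpha = grubbs_alpha
        self.residual_max = residual_max
        self.n_replicates_expected = n_replicates_expected

    def fit(self, records: pd.DataFrame, y=None, qc: list[PlateQC] | None = None):
        required = {"plate_id", "well", "role", "compound_id", "concentration_nM", "area_um2"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")

        qc_failed = {q.plate_id for q in qc or [] if not q.passed}

        self.cutoffs_ = {}
        for plate_id, grp in records.groupby("plate_id", sort=True):
            dmso = grp.loc[grp["role"] == ROLE_NEGATIVE, "area_um2"].to_numpy(float)
            rep = grubbs_filter(dmso, alpha=self.grubbs_alpha)
            co = plate_cutoff(rep.cleaned, plate_id=str(plate_id))
            co.n_removed = rep.n_removed
            self.cutoffs_[str(plate_id)] = co

        cpd = records[records["role"] == ROLE_COMPOUND].copy()
        rows = []
        for (cid, conc), grp in cpd.groupby(["compound_id", "concentration_nM"], sort=True):
            grp = grp.sort_values("plate_id")
            areas = grp["area_um2"].to_numpy(float)
            plates = grp["plate_id"].astype(str).tolist()
            cuts = np.array([self.cutoffs_[p].cutoff for p in plates])
            means = np.array([self.cutoffs_[p].dmso_mean for p in plates])
            residuals = 100.0 * areas / means
            missing_data = len(areas) < self.n_replicates_expected
            stage1 = bool(len(areas) > 0 and np.all(areas < cuts)) and not missing_data
            stage2 = bool(stage1 and np.all(residuals < self.residual_max))
            row = {
                "compound_id": cid,
                "concentration_nM": conc,
                "n_replicates": len(areas),
                "stage1_pass": stage1,
                "stage2_pass": stage2,
                "review_flag": stage2,
                "review_accepted": True,
                "final_hit": stage2,
                "missing_data": missing_data,
                "qc_failed": bool(set(plates) & qc_failed),
            }
            for k in range(self.n_replicates_expected):
                row[f"area_rep{k + 1}"] = areas[k] if k < len(areas) else np.nan
                row[f"cutoff_rep{k + 1}"] = cuts[k] if k < len(cuts) else np.nan
                row[f"residual_rep{k + 1}_pct"] = residuals[k] if k < len(residuals) else np.nan
            rows.append(row)
        self.decisions_ = pd.DataFrame(rows)
        if not self.decisions_.empty:
            lead = ["compound_id", "concentration_nM", "n_replicates"]
            rep_cols = [c for c in self.decisions_.columns if "_rep" in c]
            flags = [c for c in self.decisions_.columns if c not in lead + rep_cols]
            self.decisions_ = self.decisions_[lead + rep_cols + flags]
        self.funnel_ = {
            "tested": int(len(self.decisions_)),
            "stage1_pass": int(self.decisions_["stage1_pass"].sum()) if len(rows) else 0,
            "stage2_pass": int(self.decisions_["stage2_pass"].sum()) if len(rows) else 0,
            "final_hits": int(self.decisions_["final_hit"].sum()) if len(rows) else 0,
        }
        return self

    def apply_review(self, rejected_ids: set[str]) -> pd.DataFrame:
        """Reject reviewed compounds (the manual-inspection stand-in)."""
        d = self.decisions_
        d["review_accepted"] = ~d["compound_id"].isin(rejected_ids)
        d["final_hit"] = d["stage2_pass"] & d["review_accepted"]
        self.funnel_["final_hits"] = int(d["final_hit"].sum())
        return d

    def campaign_hits(self) -> pd.DataFrame:
        """Per-compound summary: a campaign hit passes at >= 1 concentration."""
        d = self.decisions_
        rows = []
        for cid, grp in d.groupby("compound_id", sort=True):
            hit_concs = sorted(grp.loc[grp["final_hit"], "concentration_nM"].unique().tolist())
            rows.append(
                {
                    "compound_id": cid,
                    "final_hit": bool(grp["final_hit"].any()),
                    "hit_concentrations_nM": hit_concs,
                }
            )
        return pd.DataFrame(rows)


def call_hits(
    records: pd.DataFrame,
    qc: list[PlateQC] | None = None,
    grubbs_alpha: float = 0.05,
    residual_max: float = DEFAULT_RESIDUAL_MAX,
    n_replicates_expected: int = 2,
) -> pd.DataFrame:
    """Run the full two-stage hit-calling procedure; returns the decision table."""
    caller = HitCaller(
        grubbs_alpha=grubbs_alpha,
        residual_max=residual_max,
        n_replicates_expected=n_replicates_expected,
    )
    return caller.fit(records, qc=qc).decisions_
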