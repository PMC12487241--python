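import numpy as np
import pandas as pd
import pytest

from spheroscreen.hits import HitCaller, call_hits, plate_cutoff, residual_percent
from spheroscreen.qc import PlateQC
from spheroscreen.simulate import CampaignConfig, gen_screen


class TestPlateCutoff:
    def test_hand_arithmetic(self):
        """{100, 90, 110, 95, 105}: mean 100, sample sd 7.906 -> cutoff 76.28."""
        co = plate_cutoff([100.0, 90.0, 110.0, 95.0, 105.0])
        assert co.dmso_mean == pytest.approx(100.0)
        assert co.dmso_sd == pytest.approx(7.9056942, rel=1e-6)
        assert co.cutoff == pytest.approx(76.2829175, rel=1e-6)

    def test_zero_spread_cutoff_equals_mean(self):
        co = plate_cutoff([100.0] * 6)
        assert co.cutoff == 100.0

    def test_negative_cutoff_retained(self):
        """Wildly variable DMSO gives mean - 3sd < 0; kept as-is so nothing
        can pass stage 1 on that plate."""
        co = plate_cutoff([10.0, 10.0, 100.0])
        assert co.cutoff < 0

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            plate_cutoff([5.0])


class TestResidualPercent:
    def test_ratio(self):
        assert residual_percent(40_000.0, 100_000.0) == 40.0

    def test_dmso_itself_is_100(self):
        assert residual_percent(123.0, 123.0) == 100.0

    def test_zero_area(self):
        assert residual_percent(0.0, 5.0) == 0.0

    def test_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            residual_percent(1.0, 0.0)


def records_for(areas_by_compound, dmso_a, dmso_b):
    """Two replicate plates with explicit DMSO populations and one well per
    compound per plate."""
    rows = []
    for plate, dmso in (("p1", dmso_a), ("p2", dmso_b)):
        for k, v in enumerate(dmso):
            rows.append(
                dict(plate_id=plate, well=f"B{k+2}", role="negative_control",
                     compound_id=None, concentration_nM=None, area_um2=v)
            )
        for i, (cid, areas) in enumerate(areas_by_compound.items()):
            rows.append(
                dict(plate_id=plate, well=f"C{i+3}", role="compound",
                     compound_id=cid, concentration_nM=1000.0,
                     area_um2=areas[0 if plate == "p1" else 1])
            )
    return pd.DataFrame(rows)


# DMSO populations with mean 100k and modest spread; the plate cutoffs used in
# the assertions below are recomputed from them via plate_cutoff (hand oracle).
DMSO_A = [100_000.0, 92_000.0, 108_000.0, 96_000.0, 104_000.0]
DMSO_B = [100_000.0, 94_000.0, 106_000.0, 97_000.0, 103_000.0]


class TestCallHits:
    def cutoffs(self):
        return plate_cutoff(DMSO_A).cutoff, plate_cutoff(DMSO_B).cutoff

    def test_stage1_pass_but_residual_too_high(self):
        """Areas below both cutoffs but at 70%/72% residual: stage 1 passes,
        the <50%-in-both rule fails."""
        c1, c2 = self.cutoffs()
        assert 70_000.0 < min(c1, c2)  # sanity of the construction
        dec = call_hits(records_for({"X": (70_000.0, 72_000.0)}, DMSO_A, DMSO_B)).iloc[0]
        assert dec["stage1_pass"] and not dec["stage2_pass"] and not dec["final_hit"]
        assert dec["residual_rep1_pct"] == pytest.approx(70.0)
        assert dec["residual_rep2_pct"] == pytest.approx(72.0)

    def test_full_hit(self):
        dec = call_hits(records_for({"X": (40_000.0, 45_000.0)}, DMSO_A, DMSO_B)).iloc[0]
        assert dec["stage1_pass"] and dec["stage2_pass"] and dec["final_hit"]
        assert dec["review_flag"]

    def test_one_replicate_above_cutoff_fails_stage1(self):
        """The both-duplicates rule: 40k/80k with cutoffs ~85k/~87k... the
        second replicate must also be below its own plate's cutoff."""
        c1, c2 = self.cutoffs()
        areas = (40_000.0, max(c1, c2) + 5_000.0)
        dec = call_hits(records_for({"X": areas}, DMSO_A, DMSO_B)).iloc[0]
        assert not dec["stage1_pass"] and not dec["stage2_pass"]

    def test_stage2_subset_of_stage1(self):
        cfg = CampaignConfig(n_compounds=120, noise_cv=0.08, seed=21)
        _, rec, _ = gen_screen(cfg)
        dec = call_hits(rec)
        assert not (dec["stage2_pass"] & ~dec["stage1_pass"]).any()

    def test_missing_replicate_flagged_not_dropped(self):
        rec = records_for({"X": (40_000.0, 45_000.0)}, DMSO_A, DMSO_B)
        rec = rec[~((rec["compound_id"] == "X") & (rec["plate_id"] == "p2"))]
        dec = call_hits(rec)
        assert len(dec) == 1
        assert dec.iloc[0]["missing_data"]
        assert not dec.iloc[0]["final_hit"]

    def test_qc_failed_plates_flag_decisions(self):
        rec = records_for({"X": (40_000.0, 45_000.0)}, DMSO_A, DMSO_B)
        qc = [
            PlateQC("p1", z_prime=0.9, cv_percent=5.0, n_pos=5, n_neg=5, passed=True),
            PlateQC("p2", z_prime=0.3, cv_percent=5.0, n_pos=5, n_neg=5, passed=False),
        ]
        dec = call_hits(rec, qc=qc)
        assert dec.iloc[0]["qc_failed"]

    def test_scale_invariance_per_plate(self):
        """Multiplying all areas on one plate by a > 0 changes no decision."""
        cfg = CampaignConfig(n_compounds=60, noise_cv=0.05, seed=9)
        _, rec, _ = gen_screen(cfg)
        base = call_hits(rec)
        scaled = rec.copy()
        plate = scaled["plate_id"].unique()[0]
        scaled.loc[scaled["plate_id"] == plate, "area_um2"] *= 7.3
        after = call_hits(scaled)
        cols = ["compound_id", "concentration_nM", "stage1_pass", "stage2_pass", "final_hit"]
        pd.testing.assert_frame_equal(base[cols], after[cols])

    def test_decreasing_area_never_unmakes_a_hit(self):
        rec = records_for({"X": (40_000.0, 45_000.0)}, DMSO_A, DMSO_B)
        assert call_hits(rec).iloc[0]["final_hit"]
        lower = rec.copy()
        mask = lower["compound_id"] == "X"
        lower.loc[mask, "area_um2"] *= 0.5
        assert call_hits(lower).iloc[0]["final_hit"]

    def test_grubbs_cleans_dmso_before_cutoff(self):
        """One zero-area DMSO well (segmentation failure) must not blow up
        the SD and hence the cutoff."""
        dmso_bad = DMSO_A + [0.0]
        rec = records_for({"X": (70_000.0, 72_000.0)}, dmso_bad, DMSO_B)
        caller = HitCaller().fit(rec)
        assert caller.cutoffs_["p1"].n_removed == 1
        assert caller.cutoffs_["p1"].dmso_mean == pytest.approx(100_000.0)

    def test_review_rejection_removes_final_hit(self):
        rec = records_for({"X": (40_000.0, 45_000.0), "Y": (41_000.0, 44_000.0)}, DMSO_A, DMSO_B)
        caller = HitCaller().fit(rec)
        assert caller.funnel_["final_hits"] == 2
        dec = caller.apply_review(rejected_ids={"Y"})
        assert dec.set_index("compound_id")["final_hit"].to_dict() == {"X": True, "Y": False}
        assert caller.funnel_["final_hits"] == 1

    def test_campaign_hit_at_either_concentration(self):
        cfg = CampaignConfig(
            n_compounds=4,
            noise_cv=0.0,
            seed=1,
            planted_residuals=[0.2, 0.9, 0.2, 0.9],
        )
        _, rec, _ = gen_screen(cfg)
        # make compound 3 lethal only at 10 uM
        mask = (rec["compound_id"] == "CPD003") & (rec["concentration_nM"] == 1000.0)
        rec.loc[mask, "area_um2"] = 0.9 * cfg.dmso_mean_area_um2
        caller = HitCaller().fit(rec)
        camp = caller.campaign_hits().set_index("compound_id")
        assert camp.loc["CPD001", "final_hit"]
        assert camp.loc["CPD003", "final_hit"]
        assert camp.loc["CPD003", "hit_concentrations_nM"] == [10_000.0]
        assert not camp.loc["CPD002", "final_hit"]

    def test_funnel_counts_consistent(self):
        cfg = CampaignConfig(n_compounds=100, noise_cv=0.05, seed=2)
        _, rec, _ = gen_screen(cfg)
        caller = HitCaller().fit(rec)
        f = caller.funnel_
        assert f["tested"] == len(caller.decisions_)
        assert f["tested"] >= f["stage1_pass"] >= f["stage2_pass"] >= f["final_hits"]
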