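"""Synthetic screening campaigns with known ground truth.

Every downstream stage (imaging, QC, hit calling, dose-response, synergy)
is validated against campaigns generated here: 384-well duplicate plates
with DMSO/positive-control columns and edge exclusion, per-well MIP areas
with multiplicative Gaussian noise, spheroid z-stacks, 3-fold dilution
series and 1:2 dose matrices -- all fully reproducible from a seed.

The generator reproduces the *statistical* structure the pipeline assumes
(roles, replication, noise, planted effect sizes), not spheroid biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from skimage.draw import disk

from .drc import FourPLParams, four_pl
from .imaging import ImageStack
from .plates import (
    ROLE_COMPOUND,
    ROLE_NEGATIVE,
    ROLE_POSITIVE,
    PlateLayout,
    gen_plate_layout,
    interior_capacity,
)
from .synergy import DoseMatrix, zip_expected

#: Default per-well DMSO-control MIP area (um^2): a ~250 um-radius spheroid.
DEFAULT_DMSO_AREA = 200_000.0
#: Default residual viable-area fraction of the cytotoxic positive control.
DEFAULT_POSITIVE_RESIDUAL = 0.10


class CampaignConfig(BaseModel):
    """Parameters of a synthetic primary-screen campaign.

    Compounds are screened at each concentration in duplicate (one well on
    each of ``n_replicate_plates`` plates). ``planted_residuals`` fixes each
    compound's true residual viable-area fraction; if omitted, a
    ``hit_fraction`` of compounds receives strong planted effects and the
    rest stay near the vehicle level.
    """

    model_config = {"extra": "forbid"}

    n_compounds: int = Field(gt=0)
    screen_concentrations_nM: tuple[float, ...] = (1_000.0, 10_000.0)
    dmso_mean_area_um2: float = Field(default=DEFAULT_DMSO_AREA, gt=0)
    noise_cv: float = Field(default=0.05, ge=0)
    hit_fraction: float = Field(default=0.05, ge=0, le=1)
    planted_residuals: list[float] | None = None
    positive_control_residual: float = Field(default=DEFAULT_POSITIVE_RESIDUAL, gt=0, lt=1)
    n_replicate_plates: int = Field(default=2, ge=2)
    n_rows: int = 16
    n_cols: int = 24
    seed: int = 0

    @model_validator(mode="after")
    def _check_residuals(self):
        if self.planted_residuals is not None:
            if len(self.planted_residuals) != self.n_compounds:
                raise ValueError("planted_residuals must have one entry per compound")
            for r in self.planted_residuals:
                if not 0.0 <= r <= 1.5:
                    raise ValueError("planted residuals must lie in [0, 1.5]")
        return self


@dataclass
class GroundTruth:
    """Planted truth of a synthetic campaign, for parameter-recovery tests."""

    residuals: dict[str, float] = field(default_factory=dict)
    drc_params: dict[str, FourPLParams] = field(default_factory=dict)
    synergy_delta: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"compound_id": list(self.residuals), "true_residual": list(self.residuals.values())}
        )


def _compound_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"CPD{str(i + 1).zfill(width)}" for i in range(n)]


def _draw_residuals(cfg: CampaignConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.planted_residuals is not None:
        return np.asarray(cfg.planted_residuals, dtype=float)
    n_hits = int(round(cfg.hit_fraction * cfg.n_compounds))
    res = rng.uniform(0.85, 1.15, size=cfg.n_compounds)
    hit_idx = rng.choice(cfg.n_compounds, size=n_hits, replace=False)
    res[hit_idx] = rng.uniform(0.05, 0.40, size=n_hits)
    return res


def gen_screen(config: CampaignConfig) -> tuple[list[PlateLayout], pd.DataFrame, GroundTruth]:
    """Generate a full primary-screen campaign.

    Each concentration x replicate produces as many plates as needed to hold
    all compounds (280 per 384-well plate). Well areas are drawn as
    ``true_residual * dmso_mean * (1 + eps)`` with ``eps ~ N(0, noise_cv)``
    and clipped at 0; negative controls use residual 1, positive controls
    the configured kill fraction. Identical config and seed give identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    ids = _compound_ids(config.n_compounds)
    residuals = _draw_residuals(config, rng)
    truth = GroundTruth(residuals=dict(zip(ids, residuals.tolist())))
    res_by_id = truth.residuals

    cap = interior_capacity(config.n_rows, config.n_cols)
    chunks = [ids[i : i + cap] for i in range(0, len(ids), cap)]

    layouts: list[PlateLayout] = []
    rows: list[dict] = []
    for conc in config.screen_concentrations_nM:
        conc_tag = f"{conc:g}nM"
        for rep in range(1, config.n_replicate_plates + 1):
            for p, chunk in enumerate(chunks, start=1):
                plate_id = f"{conc_tag}_rep{rep}_p{p}"
                layout = gen_plate_layout(
                    config.n_rows, config.n_cols, chunk, concentration_nM=conc, plate_id=plate_id
                )
                layouts.append(layout)
                for w in layout.wells:
                    if w.role == ROLE_COMPOUND:
                        base = res_by_id[w.compound_id]
                    elif w.role == ROLE_NEGATIVE:
                        base = 1.0
                    elif w.role == ROLE_POSITIVE:
                        base = config.positive_control_residual
                    else:
                        continue
                    eps = rng.normal(0.0, config.noise_cv) if config.noise_cv > 0 else 0.0
                    area = max(0.0, base * config.dmso_mean_area_um2 * (1.0 + eps))
                    rows.append(
                        {
                            "plate_id": plate_id,
                            "well": w.well,
                            "role": w.role,
                            "compound_id": w.compound_id,
                            "concentration_nM": w.concentration_nM,
                            "area_um2": area,
                            "replicate": rep,
                        }
                    )
    records = pd.DataFrame(rows)
    return layouts, records, truth


class FieldSizeError(ValueError):
    """Spheroid too large for the simulated field of view."""


def gen_spheroid_stack(
    true_area_um2: float,
    pixel_size_um: float = 1.0,
    n_slices: int = 40,
    z_step_um: float = 10.0,
    background_sd: float = 5.0,
    seed: int = 0,
    field_px: int = 256,
    foreground: float = 1000.0,
) -> ImageStack:
    """Synthesize a Calcein z-stack holding one quasi-spherical spheroid.

    The object is a sphere of MIP-equivalent radius sqrt(A/pi): each slice
    carries the corresponding circular cross-section, so the maximum
    projection is a disk whose pixel-counted area matches ``true_area_um2``
    up to rasterisation (well within 5% for radii above ~20 px). Gaussian
    background noise (sd in intensity units, foreground 1000) is added
    everywhere and clipped at 0.
    """
    if true_area_um2 < 0:
        raise ValueError("true_area_um2 must be >= 0")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    rng = np.random.default_rng(seed)
    vox = np.zeros((n_slices, field_px, field_px), dtype=float)
    r_px = float(np.sqrt(true_area_um2 / np.pi) / pixel_size_um)
    if 2 * r_px + 8 > field_px:
        raise FieldSizeError(
            f"spheroid radius {r_px:.0f} px does not fit the {field_px} px field"
        )
    if r_px > 0:
        center = (field_px / 2.0, field_px / 2.0)
        mid = (n_slices - 1) / 2.0
        half_span = max(mid, 1.0)
        for k in range(n_slices):
            frac = 1.0 - ((k - mid) / half_span) ** 2
            if frac <= 0:
                continue
            rk = r_px * np.sqrt(frac)
            if rk < 0.5:
                continue
            rr, cc = disk(center, rk, shape=(field_px, field_px))
            vox[k, rr, cc] = foreground
    if background_sd > 0:
        vox += rng.normal(0.0, background_sd, size=vox.shape)
        np.clip(vox, 0.0, None, out=vox)
    return ImageStack(voxels=vox, pixel_size_um=pixel_size_um, z_step_um=z_step_um)


def gen_drc_series(
    truth: FourPLParams,
    start_conc_M: float = 10e-6,
    fold: float = 3.0,
    n_dilutions: int = 10,
    noise_sd_pct: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A dilution-series response vector from a known 4PL curve.

    Concentrations form the geometric series start / fold^k, k = 0..n-1
    (the screen's design: 10 uM start, 3-fold, 10 points); responses are
    the true curve plus N(0, noise_sd_pct) noise, replicate-tiled.
    """
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if n_dilutions < 4:
        raise ValueError("need >= 4 dilutions")
    rng = np.random.default_rng(seed)
    conc = start_conc_M / fold ** np.arange(n_dilutions, dtype=float)
    conc = np.tile(conc, n_replicates)
    resp = four_pl(conc, truth.top, truth.bottom, truth.hill, truth.log10_ic50)
    if noise_sd_pct > 0:
        resp = resp + rng.normal(0.0, noise_sd_pct, size=resp.shape)
    return conc, resp


def _mono_inhibition(d, ic50_M: float, hill: float, emax: float = 1.0):
    """Monotone monotherapy inhibition fraction, 0 at zero dose."""
    d = np.asarray(d, dtype=float)
    out = np.zeros_like(d)
    nz = d > 0
    r = (d[nz] / ic50_M) ** hill
    out[nz] = emax * r / (1.0 + r)
    return out


def default_dose_axis(ic50_M: float, n_doses: int = 8) -> np.ndarray:
    """IC50-centred 1:2 dose ladder: ic50 * 2^(k - n + 4), k = 0..n-1."""
    return ic50_M * 2.0 ** (np.arange(n_doses, dtype=float) - n_doses + 4)


def gen_synergy_matrix(
    mono1: tuple[float, float],
    mono2: tuple[float, float],
    delta_true: float = 0.0,
    conc1_M: np.ndarray | None = None,
    conc2_M: np.ndarray | None = None,
    noise_sd_pct: float = 0.0,
    seed: int = 0,
) -> tuple[DoseMatrix, GroundTruth]:
    """Generate an 8x8 (default) combination matrix around a known null.

    ``mono1``/``mono2`` are (ic50_M, hill) of the single agents (full-range
    inhibition curves, 0 -> 1). Combination cells follow the independence
    surface y1 + y2 - y1*y2 plus ``delta_true``/100 (percentage points),
    clipped to [0, 1]; the zero-dose row/column carries the pure
    monotherapies. Viability noise is additive Gaussian in percent.
    """
    if not -50.0 <= delta_true <= 50.0:
        raise ValueError("delta_true must lie in [-50, 50] percentage points")
    rng = np.random.default_rng(seed)
    ic1, h1 = mono1
    ic2, h2 = mono2
    ax1 = default_dose_axis(ic1) if conc1_M is None else np.asarray(conc1_M, dtype=float)
    ax2 = default_dose_axis(ic2) if conc2_M is None else np.asarray(conc2_M, dtype=float)
    for ax in (ax1, ax2):
        ratios = ax[1:] / ax[:-1]
        if not np.allclose(ratios, 2.0):
            raise ValueError("dose axes must be geometric with ratio 2")
    c1 = np.concatenate([[0.0], ax1])
    c2 = np.concatenate([[0.0], ax2])
    y1 = _mono_inhibition(c1, ic1, h1)
    y2 = _mono_inhibition(c2, ic2, h2)
    y = zip_expected(y1[:, None], y2[None, :])
    combo = (c1[:, None] > 0) & (c2[None, :] > 0)
    y = np.where(combo, np.clip(y + delta_true / 100.0, 0.0, 1.0), y)
    viability = 100.0 * (1.0 - y)
    if noise_sd_pct > 0:
        viability = viability + rng.normal(0.0, noise_sd_pct, size=viability.shape)
    matrix = DoseMatrix(conc1_M=c1, conc2_M=c2, viability_pct=viability)
    truth = GroundTruth(synergy_delta=delta_true)
    return matrix, truth
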