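# Methods

## The screening model

The pipeline analyses screens in which each well of a 384-well plate holds one
tumour spheroid whose viable area — the thresholded area of the Calcein-AM
maximum intensity projection (MIP), in µm² — is the readout. A campaign
consists of duplicate plates (every compound appears once per replicate plate)
at each screening concentration (defaults 1 µM and 10 µM). On every plate the
interior column adjacent to each side of the compound block is reserved for
controls: DMSO 0.1% vehicle (negative, 14 wells) and a strongly cytotoxic
compound (positive, 14 wells; the emulated assay used Foretinib 30 µM). The
full plate perimeter (76 wells) is excluded from analysis because edge wells
evaporate and thermally drift differently from interior wells; the layout
therefore never assigns compounds to edge wells, which makes a separate
"re-test on supplementary plates" mechanism unnecessary — the generated
campaign already represents the post-re-test state of a real screen.

## Synthetic campaigns

`spheroscreen.simulate` generates the statistical structure the pipeline
assumes, with known ground truth:

- **Well areas.** Each compound has a true residual viable fraction r ∈
  [0, 1.5]; its well area is drawn as r·A_DMSO·(1 + ε), ε ~ N(0, CV), clipped
  at 0. Negative controls use r = 1, positive controls r = 0.10 by default
  (configurable; the value only needs to give a well-separated Z′ window).
  Defaults: A_DMSO = 200 000 µm² (a ≈250 µm-radius spheroid), CV = 5% —
  typical of a well-behaved imaging readout and consistent with plates that
  pass a 10% CV gate.
- **Image stacks.** A spheroid of target MIP area A is rendered as a sphere
  of radius √(A/π): 40 slices at 10 µm steps each carry the circular
  cross-section at that depth, at foreground intensity 1000, plus clipped
  Gaussian background noise. The MIP of the stack is a disk whose
  pixel-counted area matches A up to rasterisation (≪1% for radii above
  ~30 px).
- **Dilution series.** Geometric series (default 10 µM start, 3-fold, 10
  points, in duplicate) evaluated on a known 4PL curve plus Gaussian noise in
  percent.
- **Dose matrices.** 8×8 grids at 1:2 dilution centred on each drug's IC50
  (doses IC50·2^(−4…3)), with single-agent margins at zero dose. Combination
  inhibition follows the independence surface y₁ + y₂ − y₁y₂, optionally
  shifted by a planted offset δ/100 and clipped to [0, 1]. Monotherapies are
  full-range Hill curves (0 → 1) with slopes near 1, the standard
  single-agent assumption on the inhibition scale.

What the generator does *not* emulate: spheroid growth dynamics, spatial
plate artefacts beyond the edge effect (no row/column gradients), compound
carry-over, optical vignetting, or heteroscedastic segmentation error.
Passing tests therefore demonstrate the correctness of the decision
arithmetic and estimators under the assumed noise model, not robustness to
every artefact of a physical screen.

## Imaging readout

The MIP is the pixelwise maximum over slices. Segmentation thresholds the
MIP by Otsu's method (default) or a fixed value, removes connected
components below `min_object_px` (default 20 px) as noise specks, and sums
the area of **all** surviving segments — a fragmenting spheroid counts
fully. Because Otsu always partitions an image, even featureless noise, an
object is only accepted when the foreground/background class-mean
separation exceeds 1.75× the image SD: a mean-split Gaussian yields ≈1.6 SD
(uniform ≈1.73), while a genuine bright object yields ≥2 SD even when it
fills half the field. Featureless wells return area 0 with a `no_object` or
`flat_image` flag rather than an exception. Areas are always reported in
µm² via pixel_size²; image row 0 is the top row.

## Plate QC

Z′ = 1 − 3(σ₊ + σ₋)/|µ₊ − µ₋| with sample (n−1) SDs, computed between the
positive and negative controls of the same plate; CV = 100·σ/µ on the
negative controls (the only replicate population guaranteed on every
plate). Both control populations are Grubbs-filtered first so a single
segmentation failure cannot sink a plate. Gates are strict: Z′ > 0.5,
CV < 10%. Failing plates are flagged and their hit decisions carry a
`qc_failed` flag; nothing is silently dropped.

## Hit calling

1. **Outlier removal.** Iterative two-sided Grubbs on each plate's DMSO
   wells: at each step G = max|xᵢ − x̄|/s is compared with
   G_crit = ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n) Student-t quantile
   on n−2 df (α = 0.05). Grubbs is applied only to control populations —
   compound wells, with n = 2, cannot support it and are instead protected
   by the both-duplicates rule.
2. **Plate cutoff.** C = µ_DMSO − 3·σ_DMSO from the cleaned DMSO wells
   (sample SD). A negative cutoff is retained as-is: no well can pass
   stage 1 on such a plate.
3. **Stage 1.** Raw area < C on *every* replicate plate (each replicate
   against its own plate's cutoff).
4. **Stage 2.** Residual area 100·A/µ_DMSO < 50% on every replicate,
   evaluated for stage-1 survivors only.
5. **Review.** Stage-2 survivors are flagged for review; `apply_review`
   models the screen's manual image inspection as an editable accept/reject
   column defaulting to accept.

The 1 µM and 10 µM screens are called independently; a compound is a
campaign hit if it passes at either concentration, and the passing
concentrations are reported. Decisions are invariant to positive rescaling
of any plate's areas (both the cutoff and the residual are scale-free), and
monotone: lowering a compound's areas can never un-make a hit.

## Dose-response

Model: y = bottom + (top − bottom)/(1 + 10^((log₁₀IC₅₀ − log₁₀x)·h)) in
log10-concentration space (viability curves have h < 0 in this
parameterisation). Bounded least squares (`scipy.optimize.least_squares`)
with default bounds bottom ∈ [−10, 60]%, top ∈ [60, 130]%, |h| ≤ 10,
log₁₀IC₅₀ within the tested range ±2 decades; deterministic multi-start
over h₀ ∈ {±1, ±3} with plateaus initialised from the response extremes.
Zero-concentration (vehicle) points feed normalisation (100·raw/mean DMSO)
but never the log fit. Responses with no spread are flagged flat (no IC50,
mirroring compounds for which screens cannot derive one); non-convergence
returns a diagnosable object, never an exception. The reported IC50 is the
*relative* IC50 — the inflection, where y = (top+bottom)/2 — not the
absolute 50% crossing. Fits are exact (R² = 1 within 10⁻⁶) on noise-free
data and recover log₁₀IC₅₀ with median absolute error ≈0.013 under the
screen's validation design (10-point 3-fold duplicates, 2-point noise).

## ZIP synergy

Inhibition y = clip((100 − viability)/100, 0, 1). The scorer:

1. fits each monotherapy from the zero-dose margins with a Hill curve
   pinned at 0, ceiling free in (0, 1];
2. for each fixed dose of drug 1, refits a logistic across the drug-2 doses
   with its floor pinned to drug 1's fitted effect at that dose and its
   ceiling free in [floor, 1] (and symmetrically by columns). Leaving the
   ceiling free — the floor is the binding constraint of the construction —
   lets the directional fits track sub-null (antagonistic) surfaces that a
   ceiling fixed at 1 would systematically pull upward;
3. averages the row and column predictions into the fitted combination
   response (this makes the score exactly symmetric under drug swap);
4. δ = fitted − (ŷ₁ + ŷ₂ − ŷ₁ŷ₂); summary score = 100·mean δ over non-zero
   dose pairs; classification synergistic / additive / antagonistic at
   strict ±10.

Rows or columns whose fit fails fall back to observed values (recorded per
row/column); a matrix where every directional fit fails is flagged
low-confidence. A 3×3 maximum-mean-window score is available as a
diagnostic; the whole-matrix mean is canonical.

Calibration under the generator's conditions: 50 noise-free null matrices
all score within ±0.001; planted ±15-point offsets are recovered within ±5
(typically ±11–12 is reported) and classified correctly. Two effects
attenuate planted offsets: [0,1] clipping in the data model destroys part
of the offset wherever the null surface saturates (steep monotherapy
slopes ≫1 push many cells into saturation, where a +15 offset is partially
unrepresentable), and the pinned floors bias the directional fits toward
the null at low doses. These are properties of the inhibition scale and of
the ZIP construction itself, not of this implementation.

## Numerical and design choices

- Sample (n−1) SDs everywhere a spread is estimated.
- Strict inequalities at every published gate (Z′ > 0.5, CV < 10%,
  residual < 50%, ZIP |score| > 10).
- Grubbs requires n ≥ 3 and positive spread; otherwise a flagged no-op.
- Well naming A1–P24, row letter first; tables serialize concentrations in
  nM; all CSVs are UTF-8 with a header row.
- Determinism: every stochastic routine takes a seed and uses an
  independent `numpy.random.Generator`; identical config + seed reproduces
  byte-identical tables end to end.
- Problem sizes in the test- and acceptance-suite (320-compound campaigns,
  200 dilution series, 50 dose matrices, 30 image stacks at 256² × 40
  voxels) were chosen as the smallest designs that exercise every decision
  path with stable statistics.

## Known limitations

- The review stage is a bookkeeping flag; no image-based false-positive
  detection is attempted.
- No spatial normalisation (B-score/loess) — edge exclusion is the only
  positional correction, matching the screening procedure emulated.
- Single-channel readout; multi-channel co-culture unmixing is out of
  scope.
- ZIP scores on heavily saturated matrices (both drugs dosed far above
  IC50) are attenuated by clipping, as discussed above; dose ranges centred
  on the IC50s are assumed.
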