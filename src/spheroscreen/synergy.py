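"""Zero-interaction-potency (ZIP) synergy scoring of dose matrices.

The readout is the *inhibition* fraction y = clip((100 - viability)/100, 0, 1).
Under zero interaction two drugs combine like independent events,
y_zip = y1 + y2 - y1*y2. The ZIP delta surface is the departure of the
*fitted* combination response from that null:

1. fit a 4PL to each monotherapy (the zero-dose row and column);
2. for each fixed dose of drug 1, refit a logistic across the drug-2 doses
   with its floor pinned to the fitted monotherapy effect of drug 1 at that
   dose and its ceiling free in [floor, 1] (and symmetrically for drug 2);
3. the fitted combination response at each dose pair is the mean of the
   row-wise and column-wise predictions;
4. delta = fitted combination - y_zip of the fitted monotherapy effects.

The summary score is 100 x mean(delta) over all non-zero dose pairs;
scores above +10 are called synergistic, below -10 antagonistic, and
anything in between additive (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

#: Strict classification thresholds, in percentage points of mean delta.
SYNERGY_THRESHOLD = 10.0

CLASS_SYNERGISTIC = "synergistic"
CLASS_ANTAGONISTIC = "antagonistic"
CLASS_ADDITIVE = "additive"


def to_inhibition(viability_pct):
    """Viability % -> inhibition fraction, clipped to [0, 1]."""
    v = np.asarray(viability_pct, dtype=float)
    return np.clip((100.0 - v) / 100.0, 0.0, 1.0)


def zip_expected(y1, y2):
    """Independence (null) combination of two inhibition fractions."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    return y1 + y2 - y1 * y2


def classify_interaction(score: float) -> str:
    """Classify a summary score with the strict +/-10 point thresholds."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    if score > SYNERGY_THRESHOLD:
        return CLASS_SYNERGISTIC
    if score < -SYNERGY_THRESHOLD:
        return CLASS_ANTAGONISTIC
    return CLASS_ADDITIVE


@dataclass
class DoseMatrix:
    """A full dose-combination matrix including the single-agent margins.

    ``conc1_M``/``conc2_M`` are ascending molar dose axes whose first entry
    is 0 (the other drug alone); ``viability_pct`` has shape
    (len(conc1), len(conc2)) with [0, 0] the untreated well.
    """

    conc1_M: np.ndarray
    conc2_M: np.ndarray
    viability_pct: np.ndarray
    drug1: str = "drug1"
    drug2: str = "drug2"

    def __post_init__(self) -> None:
        self.conc1_M = np.asarray(self.conc1_M, dtype=float)
        self.conc2_M = np.asarray(self.conc2_M, dtype=float)
        self.viability_pct = np.asarray(self.viability_pct, dtype=float)
        for ax in (self.conc1_M, self.conc2_M):
            if ax[0] != 0:
                raise ValueError("each axis must start with the 0 dose")
            if np.any(np.diff(ax) <= 0):
                raise ValueError("doses must be strictly increasing")
        if self.viability_pct.shape != (self.conc1_M.size, self.conc2_M.size):
            raise ValueError("viability grid shape must match the dose axes")

    @property
    def inhibition(self) -> np.ndarray:
        return to_inhibition(self.viability_pct)

    def transpose(self) -> "DoseMatrix":
        return DoseMatrix(
            conc1_M=self.conc2_M.copy(),
            conc2_M=self.conc1_M.copy(),
            viability_pct=self.viability_pct.T.copy(),
            drug1=self.drug2,
            drug2=self.drug1,
        )

    def to_long_frame(self) -> pd.DataFrame:
        i, j = np.meshgrid(np.arange(self.conc1_M.size), np.arange(self.conc2_M.size), indexing="ij")
        return pd.DataFrame(
            {
                "conc1_nM": self.conc1_M[i.ravel()] * 1e9,
                "conc2_nM": self.conc2_M[j.ravel()] * 1e9,
                "viability_pct": self.viability_pct.ravel(),
            }
        )

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, drug1: str = "drug1", drug2: str = "drug2"):
        """Build from a long table (conc1_nM, conc2_nM, viability_pct); replicates averaged."""
        required = {"conc1_nM", "conc2_nM", "viability_pct"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        pivot = df.pivot_table(index="conc1_nM", columns="conc2_nM", values="viability_pct", aggfunc="mean")
        pivot = pivot.sort_index().sort_index(axis=1)
        if pivot.isna().any().any():
            raise ValueError("dose matrix has missing dose pairs")
        return cls(
            conc1_M=pivot.index.to_numpy(float) * 1e-9,
            conc2_M=pivot.columns.to_numpy(float) * 1e-9,
            viability_pct=pivot.to_numpy(float),
            drug1=drug1,
            drug2=drug2,
        )


def _hill_fraction(d, lam, log10_m, floor, emax=1.0):
    """Constrained logistic on the inhibition-fraction scale: floor -> emax."""
    r = (np.asarray(d, dtype=float) / 10.0**log10_m) ** lam
    return floor + (emax - floor) * r / (1.0 + r)


def _fit_hill_fraction(d, y, floor: float, x0=(1.0, None)):
    """Least-squares fit of (lambda, log10 m, emax) with the floor pinned.

    The floor (zero-dose response) is fixed at the other drug's fitted
    monotherapy effect; the ceiling is free in [floor, 1]. Returns
    (lambda, log10_m, emax, success). Multi-start over slope initials;
    deterministic.
    """
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)
    lo = np.array([0.05, np.log10(d.min()) - 3.0, floor + 1e-9])
    hi = np.array([10.0, np.log10(d.max()) + 3.0, 1.0])
    m0 = x0[1] if x0[1] is not None else float(np.log10(np.median(d)))
    m0 = float(np.clip(m0, lo[1], hi[1]))

    def residuals(p):
        return _hill_fraction(d, p[0], p[1], floor, p[2]) - y

    best = None
    for lam0 in (x0[0], 0.5, 2.0):
        try:
            sol = least_squares(
                residuals,
                np.clip([lam0, m0, 1.0], lo, hi),
                bounds=(lo, hi),
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return np.nan, np.nan, np.nan, False
    return float(best.x[0]), float(best.x[1]), float(best.x[2]), bool(best.success)


@dataclass
class MonotherapyFit:
    """Fitted single-agent inhibition curve (floor 0, ceiling free in [0, 1])."""

    emax: float
    lam: float
    log10_m: float
    success: bool

    def predict(self, d):
        r = (np.asarray(d, dtype=float) / 10.0**self.log10_m) ** self.lam
        return self.emax * r / (1.0 + r)


def _fit_monotherapy(d, y) -> MonotherapyFit:
    """4PL monotherapy fit on the fraction scale with floor pinned at 0."""
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)
    lo = np.array([1e-6, 0.05, np.log10(d.min()) - 3.0])
    hi = np.array([1.0, 10.0, np.log10(d.max()) + 3.0])

    def residuals(p):
        emax, lam, lm = p
        r = (d / 10.0**lm) ** lam
        return emax * r / (1.0 + r) - y

    best = None
    m0 = float(np.log10(np.median(d)))
    e0 = float(np.clip(y.max(), 1e-6, 1.0))
    for lam0 in (1.0, 0.5, 2.0):
        try:
            sol = least_squares(
                residuals,
                np.clip([e0, lam0, m0], lo, hi),
                bounds=(lo, hi),
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return MonotherapyFit(emax=float(y.max()), lam=1.0, log10_m=m0, success=False)
    return MonotherapyFit(
        emax=float(best.x[0]), lam=float(best.x[1]), log10_m=float(best.x[2]), success=bool(best.success)
    )


@dataclass
class ZIPResult:
    """Delta surface, summary score and classification for one dose matrix."""

    delta: np.ndarray  # fractions, shape (n1-1, n2-1) over non-zero dose pairs
    summary_score: float  # percentage points
    classification: str
    mono1: MonotherapyFit
    mono2: MonotherapyFit
    fallback_rows: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    fallback_cols: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    low_confidence: bool = False


class ZIPScorer(BaseEstimator):
    """Fit the ZIP delta surface of a :class:`DoseMatrix`.

    Parameters
    ----------
    min_doses : int
        Minimum number of non-zero doses required on each axis.

    Attributes (after ``fit``)
    --------------------------
    delta_ : ndarray
        Delta surface (fractions) over the non-zero dose pairs.
    summary_score_ : float
        100 x mean(delta_).
    classification_ : str
        synergistic / additive / antagonistic at strict +/-10.
    result_ : ZIPResult
    """

    def __init__(self, min_doses: int = 4):
        self.min_doses = min_doses

    def fit(self, X: DoseMatrix, y=None):
        m = X
        d1 = m.conc1_M[1:]
        d2 = m.conc2_M[1:]
        if d1.size < self.min_doses or d2.size < self.min_doses:
            raise ValueError(f"need >= {self.min_doses} non-zero doses per axis")
        inh = m.inhibition
        mono1 = _fit_monotherapy(d1, inh[1:, 0])
        mono2 = _fit_monotherapy(d2, inh[0, 1:])
        y1 = np.clip(mono1.predict(d1), 0.0, 1.0 - 1e-9)  # fitted drug-1 effects (floors of row fits)
        y2 = np.clip(mono2.predict(d2), 0.0, 1.0 - 1e-9)

        n1, n2 = d1.size, d2.size
        row_pred = np.empty((n1, n2))
        col_pred = np.empty((n1, n2))
        fb_rows = np.zeros(n1, dtype=bool)
        fb_cols = np.zeros(n2, dtype=bool)
        # row-wise: dose of drug 1 fixed, logistic across drug-2 doses
        for i in range(n1):
            obs = inh[1 + i, 1:]
            lam, lm, emax, ok = _fit_hill_fraction(d2, obs, floor=y1[i], x0=(mono2.lam, mono2.log10_m))
            if ok:
                row_pred[i] = _hill_fraction(d2, lam, lm, y1[i], emax)
            else:
                row_pred[i] = obs
                fb_rows[i] = True
        # column-wise: dose of drug 2 fixed, logistic across drug-1 doses
        for j in range(n2):
            obs = inh[1:, 1 + j]
            lam, lm, emax, ok = _fit_hill_fraction(d1, obs, floor=y2[j], x0=(mono1.lam, mono1.log10_m))
            if ok:
                col_pred[:, j] = _hill_fraction(d1, lam, lm, y2[j], emax)
            else:
                col_pred[:, j] = obs
                fb_cols[j] = True

        fitted = 0.5 * (row_pred + col_pred)
        null = zip_expected(y1[:, None], y2[None, :])
        delta = fitted - null
        score = float(100.0 * delta.mean())
        self.result_ = ZIPResult(
            delta=delta,
            summary_score=score,
            classification=classify_interaction(score),
            mono1=mono1,
            mono2=mono2,
            fallback_rows=fb_rows,
            fallback_cols=fb_cols,
            low_confidence=bool(fb_rows.all() and fb_cols.all()),
        )
        self.delta_ = delta
        self.summary_score_ = score
        self.classification_ = self.result_.classification
        return self

    def max_window_score(self, size: int = 3) -> float:
        """Diagnostic: largest mean delta (x100) over any size x size sub-window."""
        d = self.delta_
        if d.shape[0] < size or d.shape[1] < size:
            raise ValueError("delta surface smaller than the window")
        best = -np.inf
        for i in range(d.shape[0] - size + 1):
            for j in range(d.shape[1] - size + 1):
                best = max(best, d[i : i + size, j : j + size].mean())
        return float(100.0 * best)


def zip_delta_surface(matrix: DoseMatrix, min_doses: int = 4) -> np.ndarray:
    """Delta surface (fractions) over the non-zero dose pairs of ``matrix``."""
    return ZIPScorer(min_doses=min_doses).fit(matrix).delta_


def zip_summary(delta: np.ndarray) -> float:
    """Summary synergy score: 100 x mean delta over all non-zero dose pairs."""
    delta = np.asarray(delta, dtype=float)
    if delta.size == 0:
        raise ValueError("empty delta surface")
    return float(100.0 * delta.mean())


def score_matrix(matrix: DoseMatrix, min_doses: int = 4) -> ZIPResult:
    """One-call ZIP analysis of a dose matrix."""
    return ZIPScorer(min_doses=min_doses).fit(matrix).result_
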