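"""Four-parameter logistic dose-response fitting and relative IC50.

The model is the variable-slope logistic in log10 concentration,

    y = bottom + (top - bottom) / (1 + 10**((log10_ic50 - log10 x) * hill))

so the fitted curve passes through (top + bottom)/2 exactly at the
inflection concentration -- the *relative* IC50 reported throughout.
Viability curves (100% at vehicle, falling with dose) have negative hill
in this parameterisation; inhibition curves have positive hill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

#: Default parameter bounds (percent-response scale).
DEFAULT_BOUNDS = {
    "bottom": (-10.0, 60.0),
    "top": (60.0, 130.0),
    "hill": (-10.0, 10.0),
}
#: log10_ic50 is bounded to [min conc / 100, max conc * 100].
LOG_IC50_PAD = 2.0

#: Responses with spread below this (percent points) are flagged flat.
FLAT_SD = 1e-9


@dataclass(frozen=True)
class FourPLParams:
    """Ground-truth or fitted 4PL parameters (top/bottom in %, ic50 in molar)."""

    top: float
    bottom: float
    hill: float
    ic50_M: float

    def __post_init__(self) -> None:
        if self.ic50_M <= 0:
            raise ValueError("ic50 must be positive")
        if self.top < self.bottom:
            raise ValueError("top must be >= bottom")

    @property
    def log10_ic50(self) -> float:
        return float(np.log10(self.ic50_M))


def four_pl(conc_M, top: float, bottom: float, hill: float, log10_ic50: float):
    """Evaluate the variable-slope logistic at molar concentrations."""
    logc = np.log10(np.asarray(conc_M, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log10_ic50 - logc) * hill))


def normalize_viability(raw_signals, dmso_signals):
    """Percent-of-DMSO normalisation: 100 * raw / mean(DMSO)."""
    dmso = np.asarray(dmso_signals, dtype=float)
    mean = dmso.mean()
    if not mean > 0:
        raise ValueError("DMSO mean must be positive")
    return 100.0 * np.asarray(raw_signals, dtype=float) / mean


class FlatCurveError(ValueError):
    """IC50 requested from a flat or unconverged fit."""


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Four-parameter logistic dose-response regressor.

    Fits responses (percent of vehicle control) against molar
    concentrations by least squares in log10-concentration space, with a
    deterministic multi-start over the hill sign so ascending and
    descending curves are both reached from fixed initials.

    Parameters
    ----------
    bottom_bounds, top_bounds : (low, high)
        Plateau bounds in percent.
    max_abs_hill : float
        Hill-slope magnitude bound.
    log_ic50_pad : float
        log10_ic50 is constrained to the tested range widened by this many
        decades on each side.

    Attributes (after ``fit``)
    --------------------------
    top_, bottom_, hill_, log10_ic50_, ic50_M_ : float
        Fitted parameters; ``ic50_M_`` is the relative IC50 in molar.
    r_squared_ : float
        1 - SS_res/SS_tot on the training data.
    converged_ : bool
    flat_ : bool
        True when the responses carry no dose information (no IC50).
    """

    def __init__(
        self,
        bottom_bounds: tuple = DEFAULT_BOUNDS["bottom"],
        top_bounds: tuple = DEFAULT_BOUNDS["top"],
        max_abs_hill: float = 10.0,
        log_ic50_pad: float = LOG_IC50_PAD,
    ):
        self.bottom_bounds = bottom_bounds
        self.top_bounds = top_bounds
        self.max_abs_hill = max_abs_hill
        self.log_ic50_pad = log_ic50_pad

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).ravel()
        resp = np.asarray(y, dtype=float).ravel()
        if conc.shape != resp.shape:
            raise ValueError("X and y must have matching lengths")
        if not np.all(np.isfinite(resp)):
            raise ValueError("responses must be finite")
        pos = conc > 0
        conc, resp = conc[pos], resp[pos]  # vehicle (0-dose) points never enter the log fit
        if np.unique(conc).size < 4:
            raise ValueError("need >= 4 distinct positive concentrations")
        logc = np.log10(conc)
        self.n_points_ = int(conc.size)

        if resp.std(ddof=0) <= FLAT_SD:
            self.flat_ = True
            self.converged_ = False
            self.top_ = self.bottom_ = float(resp.mean())
            self.hill_ = 0.0
            self.log10_ic50_ = np.nan
            self.ic50_M_ = np.nan
            self.r_squared_ = np.nan
            return self
        self.flat_ = False

        lo_b, hi_b = self.bottom_bounds
        lo_t, hi_t = self.top_bounds
        lo_l = logc.min() - self.log_ic50_pad
        hi_l = logc.max() + self.log_ic50_pad
        lower = np.array([lo_t, lo_b, -self.max_abs_hill, lo_l])
        upper = np.array([hi_t, hi_b, self.max_abs_hill, hi_l])

        top0 = float(np.clip(resp.max(), lo_t, hi_t))
        bot0 = float(np.clip(resp.min(), lo_b, hi_b))
        mid = (resp.max() + resp.min()) / 2.0
        l0 = float(logc[np.argmin(np.abs(resp - mid))])
        l0 = float(np.clip(l0, lo_l, hi_l))

        def residuals(p):
            top, bottom, hill, lic = p
            return bottom + (top - bottom) / (1.0 + 10.0 ** ((lic - logc) * hill)) - resp

        best = None
        for hill0 in (1.0, -1.0, 3.0, -3.0):  # deterministic multi-start over slope
            x0 = np.clip(np.array([top0, bot0, hill0, l0]), lower, upper)
            try:
                sol = least_squares(residuals, x0, bounds=(lower, upper), xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            self.converged_ = False
            self.top_ = self.bottom_ = np.nan
            self.hill_ = np.nan
            self.log10_ic50_ = np.nan
            self.ic50_M_ = np.nan
            self.r_squared_ = np.nan
            return self

        self.top_, self.bottom_, self.hill_, self.log10_ic50_ = (float(v) for v in best.x)
        self.ic50_M_ = float(10.0**self.log10_ic50_)
        ss_res = float(2 * best.cost)
        ss_tot = float(((resp - resp.mean()) ** 2).sum())
        self.r_squared_ = 1.0 - ss_res / ss_tot
        self.converged_ = bool(best.success)
        return self

    def predict(self, X):
        conc = np.asarray(X, dtype=float).ravel()
        if self.flat_:
            return np.full(conc.shape, self.top_)
        return four_pl(conc, self.top_, self.bottom_, self.hill_, self.log10_ic50_)

    @property
    def params_(self) -> FourPLParams:
        top, bottom = sorted((self.top_, self.bottom_))[::-1]
        return FourPLParams(top=top, bottom=bottom, hill=self.hill_, ic50_M=self.ic50_M_)


def fit_4pl(concentrations_M, responses_pct, **kwargs) -> FourParamLogistic:
    """Fit a :class:`FourParamLogistic`; never raises on non-convergence."""
    return FourParamLogistic(**kwargs).fit(concentrations_M, responses_pct)


def relative_ic50(fit: FourParamLogistic) -> float:
    """Relative IC50 (molar): the inflection concentration of the fitted curve.

    This is the concentration giving (top + bottom)/2 -- not the absolute
    50%-response crossing, which differs whenever the plateaus are not
    exactly 100 and 0.
    """
    if getattr(fit, "flat_", True) or not np.isfinite(fit.ic50_M_):
        raise FlatCurveError("relative IC50 undefined: flat or unconverged fit")
    return float(fit.ic50_M_)


def fit_drc_table(df: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Fit every compound in a long table (compound_id, concentration_nM, response_pct).

    Returns one row per compound with the fitted parameters, relative IC50
    in nM, R^2 and the converged/flat flags; non-convergent compounds are
    reported, never dropped.
    """
    required = {"compound_id", "concentration_nM", "response_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for cid, grp in df.groupby("compound_id", sort=True):
        conc_M = grp["concentration_nM"].to_numpy(float) * 1e-9
        try:
            fit = fit_4pl(conc_M, grp["response_pct"].to_numpy(float), **kwargs)
            rows.append(
                {
                    "compound_id": cid,
                    "top": fit.top_,
                    "bottom": fit.bottom_,
                    "hill": fit.hill_,
                    "ic50_nM": fit.ic50_M_ * 1e9 if np.isfinite(fit.ic50_M_) else np.nan,
                    "r2": fit.r_squared_,
                    "converged": fit.converged_,
                    "flat": fit.flat_,
                    "n_points": fit.n_points_,
                    "reason": "" if fit.converged_ else ("flat_response" if fit.flat_ else "no_convergence"),
                }
            )
        except ValueError as e:
            rows.append(
                {
                    "compound_id": cid,
                    "top": np.nan,
                    "bottom": np.nan,
                    "hill": np.nan,
                    "ic50_nM": np.nan,
                    "r2": np.nan,
                    "converged": False,
                    "flat": False,
                    "n_points": len(grp),
                    "reason": str(e),
                }
            )
    return pd.DataFrame(rows)
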