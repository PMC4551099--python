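"""Growth-temperature inference from 16S rRNA G+C content.

The G+C fraction (P_GC) of a defined internal region of the 16S rRNA gene
correlates strongly and positively with a prokaryote's growth temperature:
thermophiles and hyperthermophiles carry GC-richer rRNA stems than
mesophiles and psychrophiles. Linear regressions of minimum, optimum and
maximum growth temperature on P_GC therefore let one place uncultured
phylotypes on a thermal scale from sequence alone.

The regression coefficients are recovered here by ordinary least squares
on a packaged calibration table of (P_GC, T_min, T_opt, T_max) pairs for
reference phylotypes and strains spanning ~52-66% GC (roughly 2-93 deg C).
Parenthetical experimentally observed temperatures of cultured strains are
kept alongside for comparison but never enter the fit.

`GrowthTemperatureRegressor` follows the scikit-learn estimator API:
``fit(p_gc, temps)`` then ``predict(p_gc)`` returning the three
temperatures per query.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "TEMP_KINDS",
    "LIFESTYLES",
    "ThermalPrediction",
    "load_calibration",
    "GrowthTemperatureRegressor",
    "fit_temp_model",
    "predict_growth_temp",
    "classify_lifestyle",
    "loo_validate",
    "community_thermal_profile",
]

TEMP_KINDS = ("t_min", "t_opt", "t_max")

#: Conventional optimum-temperature cutoffs (deg C) between thermal classes.
DEFAULT_LIFESTYLE_THRESHOLDS = (15.0, 45.0, 80.0)
LIFESTYLES = ("psychrophile", "mesophile", "thermophile", "hyperthermophile")

#: Soft calibration hull; predictions outside it extrapolate and warn.
CALIBRATION_HULL = (40.0, 80.0)


@dataclass(frozen=True)
class ThermalPrediction:
    p_gc: float
    t_min: int
    t_opt: int
    t_max: int
    lifestyle: str


def load_calibration(path=None) -> pd.DataFrame:
    """Load a calibration table (packaged default if `path` is None).

    Columns: label, group, p_gc, t_min, t_opt, t_max, observed_min,
    observed_opt, observed_max, n_clones, genome_derived.
    """
    if path is None:
        ref = importlib.resources.files("clonelib.data") / "growth_temp_calibration.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"label", "p_gc", *TEMP_KINDS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration table missing columns {sorted(missing)}")
    bad = df[~(df["t_min"] <= df["t_opt"]) | ~(df["t_opt"] <= df["t_max"])]
    if len(bad):
        raise ValueError(f"calibration rows violate t_min <= t_opt <= t_max: "
                         f"{bad['label'].tolist()}")
    return df


class GrowthTemperatureRegressor(BaseEstimator, RegressorMixin):
    """OLS of (T_min, T_opt, T_max) on 16S-region G+C percentage.

    Attributes (after fit)
    ----------------------
    slopes_, intercepts_ : ndarray, shape (3,)
        One line per temperature kind, order (min, opt, max); slopes in
        deg C per %GC, intercepts in deg C. Slopes are validated strictly
        positive (a negative slope signals corrupted calibration input).
    rmse_, max_residual_ : ndarray, shape (3,)
        Fit diagnostics on the calibration set, deg C.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        if isinstance(y, pd.DataFrame):
            y = y[list(TEMP_KINDS)].to_numpy()
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 3:
            raise ValueError("y must have three columns (t_min, t_opt, t_max)")
        if len(x) != len(y):
            raise ValueError("X and y length mismatch")
        if len(np.unique(x)) < 3:
            raise ValueError("need at least 3 rows with distinct P_GC to fit")
        A = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        slopes, intercepts = coef[0], coef[1]
        if np.any(slopes <= 0):
            raise ValueError(
                f"fitted slope(s) not positive ({slopes}); the GC-temperature "
                "correlation is positive - check the calibration input"
            )
        resid = y - A @ coef
        self.slopes_ = slopes
        self.intercepts_ = intercepts
        self.rmse_ = np.sqrt((resid**2).mean(axis=0))
        self.max_residual_ = np.abs(resid).max(axis=0)
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        """Unrounded (n, 3) array of (T_min, T_opt, T_max) in deg C."""
        check_is_fitted(self, "slopes_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return x[:, None] * self.slopes_[None, :] + self.intercepts_[None, :]


def fit_temp_model(rows: pd.DataFrame) -> GrowthTemperatureRegressor:
    """Fit the temperature regressions on a calibration table.

    Uses the predicted (non-parenthetical) temperature columns only;
    observed strain temperatures are comparison data, not training data.
    """
    return GrowthTemperatureRegressor().fit(rows["p_gc"], rows[list(TEMP_KINDS)])


def classify_lifestyle(t_opt: float, thresholds=DEFAULT_LIFESTYLE_THRESHOLDS) -> str:
    """Thermal lifestyle from the optimum growth temperature.

    psychrophile < thresholds[0] <= mesophile < thresholds[1] <=
    thermophile < thresholds[2] <= hyperthermophile.
    """
    if not np.isfinite(t_opt):
        raise ValueError("t_opt must be finite")
    lo, mid, hi = thresholds
    if t_opt < lo:
        return "psychrophile"
    if t_opt < mid:
        return "mesophile"
    if t_opt < hi:
        return "thermophile"
    return "hyperthermophile"


def predict_growth_temp(
    p_gc: float,
    model: GrowthTemperatureRegressor,
    lifestyle_thresholds=DEFAULT_LIFESTYLE_THRESHOLDS,
) -> ThermalPrediction:
    """Predict the thermal triple at one P_GC, rounded to whole deg C."""
    check_is_fitted(model, "slopes_")
    if not CALIBRATION_HULL[0] < p_gc < CALIBRATION_HULL[1]:
        warnings.warn(
            f"P_GC {p_gc} outside the calibration hull "
            f"{CALIBRATION_HULL}; prediction is an extrapolation",
            stacklevel=2,
        )
    tmin, topt, tmax = model.predict([p_gc])[0]
    return ThermalPrediction(
        p_gc=p_gc,
        t_min=int(round(tmin)),
        t_opt=int(round(topt)),
        t_max=int(round(tmax)),
        lifestyle=classify_lifestyle(topt, lifestyle_thresholds),
    )


def loo_validate(rows: pd.DataFrame) -> pd.DataFrame:
    """Leave-one-out validation of the calibration regressions.

    Each row is predicted from a refit on the remaining rows; the report
    lists predicted values and residuals per temperature kind.
    """
    if len(rows) < 4:
        raise ValueError("need at least 4 calibration rows for leave-one-out")
    if len(rows) == 4:
        warnings.warn("leave-one-out on 4 rows uses 3-point fits", stacklevel=2)
    rows = rows.reset_index(drop=True)
    out = []
    for i in range(len(rows)):
        train = rows.drop(index=i)
        model = fit_temp_model(train)
        pred = model.predict([rows.at[i, "p_gc"]])[0]
        rec = {"label": rows.at[i, "label"], "p_gc": rows.at[i, "p_gc"]}
        for k, kind in enumerate(TEMP_KINDS):
            rec[f"{kind}_pred"] = pred[k]
            rec[f"{kind}_residual"] = pred[k] - rows.at[i, kind]
        out.append(rec)
    return pd.DataFrame(out)


def community_thermal_profile(t_opts, weights) -> float:
    """Clone-weighted mean optimum temperature of a taxon group, whole deg C."""
    t = np.asarray(t_opts, dtype=float)
    w = np.asarray(weights, dtype=float)
    if t.size == 0 or w.sum() <= 0:
        raise ValueError("need at least one prediction with positive total weight")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    return round(float((t * w).sum() / w.sum()))
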