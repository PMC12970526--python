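"""Calibration-curve fitting, inversion and error propagation.

Reference GUVs of known cholesterol content give a calibration line

    y = c + m * x,     x = mol% cholesterol, y = GP or lifetime readout,

fitted by weighted least squares (weights 1/SD^2 on the condition means by
default; equal weights reduce to OLS).  An unknown vesicle population with
mean readout y is mapped back through the line, x_hat = (y - c) / m, and the
uncertainty is propagated to first order (delta method):

    sigma_x^2 = (sigma_y^2 + se_c^2) / m^2
              + x_hat^2 * se_m^2 / m^2
              + 2 * x_hat * cov(c, m) / m^2,

with sigma_y the standard error of the mean readout (SD/sqrt(n)).  Group
differences are tested with the Kruskal-Wallis rank test (the per-GUV
readout distributions are generally non-normal with unequal variances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class CalibrationPoint:
    """One reference condition: known mol% cholesterol and its mean readout."""

    chol_molpct: float
    readout_mean: float
    readout_sd: float
    n_vesicles: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.chol_molpct <= 100.0:
            raise ValueError("chol_molpct must lie in [0, 100]")
        if self.readout_sd < 0:
            raise ValueError("readout_sd must be >= 0")
        if self.n_vesicles < 1:
            raise ValueError("n_vesicles must be >= 1")


@dataclass(frozen=True)
class CholesterolEstimate:
    """Inverted calibration estimate with delta-method uncertainty (mol%)."""

    chol_molpct_hat: float
    se: float
    readout: float
    readout_sem: float
    components: dict  # variance contributions, mol%^2

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be >= 0")


@dataclass
class CalibrationResults:
    """Fitted calibration line with parameter uncertainties."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    cov_intercept_slope: float
    weighting: str
    n_points: int
    residual_scatter: float  # weighted root-mean-square residual
    modality: str = ""

    MIN_SLOPE = 1e-12

    # -- inversion ---------------------------------------------------------

    def invert(self, readout: float) -> float:
        """x_hat = (y - c) / m."""
        if abs(self.slope) < self.MIN_SLOPE:
            raise ValueError("slope too close to zero: inversion is ill-conditioned")
        return float((readout - self.intercept) / self.slope)

    def propagate(
        self,
        readout: float,
        readout_sd: float = 0.0,
        n_vesicles: int = 1,
        include_covariance: bool = True,
    ) -> CholesterolEstimate:
        """Delta-method propagation of the inverted estimate.

        ``readout_sd`` is the per-GUV standard deviation of the condition;
        its standard error SD/sqrt(n) enters the propagation, alongside the
        standard errors of intercept and slope (and their covariance unless
        ``include_covariance`` is off).
        """
        if readout_sd < 0:
            raise ValueError("readout_sd must be >= 0")
        if n_vesicles < 1:
            raise ValueError("n_vesicles must be >= 1")
        x_hat = self.invert(readout)
        sem_y = readout_sd / np.sqrt(n_vesicles)
        m2 = self.slope**2
        comp = {
            "readout": sem_y**2 / m2,
            "intercept": self.se_intercept**2 / m2,
            "slope": x_hat**2 * self.se_slope**2 / m2,
            "covariance": (
                2.0 * x_hat * self.cov_intercept_slope / m2 if include_covariance else 0.0
            ),
        }
        var = sum(comp.values())
        if var < 0:
            warnings.warn(
                "covariance term drove the propagated variance negative; "
                "falling back to the covariance-free sum",
                stacklevel=2,
            )
            comp["covariance"] = 0.0
            var = sum(comp.values())
        return CholesterolEstimate(
            chol_molpct_hat=x_hat,
            se=float(np.sqrt(var)),
            readout=float(readout),
            readout_sem=float(sem_y),
            components=comp,
        )

    def summary(self) -> str:
        lines = [
            f"Linear calibration ({self.modality or 'readout'} vs mol% cholesterol)",
            "=" * 52,
            f"weighting          : {self.weighting}",
            f"n calibration pts  : {self.n_points}",
            f"intercept c        : {self.intercept:+.4f} +/- {self.se_intercept:.4f}",
            f"slope m            : {self.slope:+.5f} +/- {self.se_slope:.5f} per mol%",
            f"cov(c, m)          : {self.cov_intercept_slope:+.3e}",
            f"wtd RMS residual   : {self.residual_scatter:.4f}",
        ]
        return "\n".join(lines)


class LinearCalibration:
    """Weighted linear model readout = c + m * (mol% cholesterol).

    Built from :class:`CalibrationPoint` objects or a DataFrame with columns
    ``chol_molpct``, ``readout_mean``, ``readout_sd`` (and optionally
    ``n_vesicles``); ``fit()`` returns :class:`CalibrationResults`.
    """

    def __init__(self, points: list[CalibrationPoint], modality: str = "") -> None:
        if len(points) < 2:
            raise ValueError("need at least 2 calibration points")
        if len(points) == 2:
            warnings.warn("only 2 calibration points: zero residual degrees of freedom",
                          stacklevel=2)
        x = np.array([p.chol_molpct for p in points], dtype=float)
        if np.unique(x).size < 2:
            raise ValueError("calibration points must span at least 2 distinct mol% values")
        self.points = list(points)
        self.modality = modality
        self.x = x
        self.y = np.array([p.readout_mean for p in points], dtype=float)
        self.sd = np.array([p.readout_sd for p in points], dtype=float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, modality: str = "") -> "LinearCalibration":
        points = [
            CalibrationPoint(
                chol_molpct=row["chol_molpct"],
                readout_mean=row["readout_mean"],
                readout_sd=row["readout_sd"],
                n_vesicles=int(row.get("n_vesicles", 1)),
            )
            for _, row in df.iterrows()
        ]
        return cls(points, modality=modality)

    def fit(self, weighting: str = "inverse_variance") -> CalibrationResults:
        if weighting == "inverse_variance":
            if np.any(self.sd <= 0):
                raise ValueError(
                    "a calibration point has SD = 0: inverse-variance weights are "
                    "undefined; use weighting='equal'"
                )
            weights = 1.0 / self.sd**2
        elif weighting == "equal":
            weights = np.ones_like(self.y)
        else:
            raise ValueError("weighting must be 'inverse_variance' or 'equal'")
        design = sm.add_constant(self.x)
        res = sm.WLS(self.y, design, weights=weights).fit()
        cov = np.asarray(res.cov_params())
        resid = self.y - res.fittedvalues
        wrms = float(np.sqrt(np.average(resid**2, weights=weights)))
        return CalibrationResults(
            intercept=float(res.params[0]),
            slope=float(res.params[1]),
            se_intercept=float(res.bse[0]),
            se_slope=float(res.bse[1]),
            cov_intercept_slope=float(cov[0, 1]),
            weighting=weighting,
            n_points=len(self.points),
            residual_scatter=wrms,
            modality=self.modality,
        )


def fit_calibration(
    points: list[CalibrationPoint],
    weighting: str = "inverse_variance",
    modality: str = "",
) -> CalibrationResults:
    """Fit the calibration line; see :class:`LinearCalibration`."""
    return LinearCalibration(points, modality=modality).fit(weighting=weighting)


def invert_calibration(model: CalibrationResults, readout: float) -> float:
    """Mol% cholesterol for a readout: x_hat = (y - c) / m."""
    return model.invert(readout)


def propagate_error(
    model: CalibrationResults,
    readout: float,
    readout_sd: float,
    n_vesicles: int,
    include_covariance: bool = True,
) -> CholesterolEstimate:
    """Inverted estimate with delta-method standard error; see the module docstring."""
    return model.propagate(readout, readout_sd, n_vesicles, include_covariance)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least 1 value")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def estimate_conditions(
    records: pd.DataFrame,
    model: CalibrationResults,
    value_col: str = "value",
    condition_col: str = "condition",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-condition cholesterol estimates from per-GUV readout records.

    ``records`` needs one row per vesicle with its readout and condition
    label.  Returns ``(condition_table, per_guv, tests)`` where
    ``condition_table`` carries the mean readout, SEM, inverted estimate and
    propagated error per condition, ``per_guv`` the per-vesicle inverted
    estimates, and ``tests`` the Kruskal-Wallis result across conditions on
    the raw readouts.
    """
    if records.empty:
        raise ValueError("no records")
    rows = []
    per_guv = records.copy()
    per_guv["chol_molpct_hat"] = [model.invert(v) for v in per_guv[value_col]]
    groups, labels = [], []
    for cond, grp in records.groupby(condition_col, sort=False):
        vals = grp[value_col].to_numpy(dtype=float)
        n = vals.size
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else np.nan
        flagged = n < 2
        est = model.propagate(mean, 0.0 if flagged else sd, max(n, 1))
        rows.append(
            {
                condition_col: cond,
                "n_vesicles": n,
                "readout_mean": mean,
                "readout_sd": sd,
                "readout_sem": sd / np.sqrt(n) if n > 1 else np.nan,
                "chol_molpct_hat": est.chol_molpct_hat,
                "chol_molpct_se": est.se if not flagged else np.nan,
                "flagged_small_n": flagged,
            }
        )
        groups.append(vals)
        labels.append(cond)
    tests = {}
    if len(groups) >= 2 and all(g.size >= 1 for g in groups):
        h, p = kruskal_wallis(groups)
        tests = {"kruskal_wallis_H": h, "kruskal_wallis_p": p, "groups": labels}
    return pd.DataFrame(rows), per_guv, tests
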