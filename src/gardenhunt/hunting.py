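"""Hunting-site selection analyses.

Tests of whether hunters choose localities by accessibility (closeness to a
conuco) or by habitat/abundance: a logistic regression of the binary
hunting flag at each camera site on raw-scale covariates (tree cover %,
distance to river and to conuco in metres), Pearson chi-square contingency
tests of habitat and season preferences across communities, and a
descriptive comparison of model-predicted abundance between hunted and
unhunted sites (the comparison is reported descriptively, without a test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GlmResult",
    "ContingencyResult",
    "fit_hunting_glm",
    "chi2_contingency",
    "compare_lambda_by_hunting",
]

HUNTING_COVARIATES = ("tree_buffer", "dist_conuco", "dist_river")


@dataclass
class GlmResult:
    """Logistic-regression summary for hunting occurrence."""

    params: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    null_deviance: float
    deviance: float
    aic: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.se, "z": self.z, "p": self.p}
        )


def fit_hunting_glm(
    site_table: pd.DataFrame,
    covariates: tuple[str, ...] = HUNTING_COVARIATES,
) -> GlmResult:
    """Logistic regression of the hunting flag on site covariates.

    Covariates stay on their raw scales (percent, metres), so per-metre
    distance coefficients are of order 1e-3 or smaller.  Fitting is
    maximum likelihood via iteratively reweighted least squares; Wald z and
    two-sided p-values are reported per term.
    """
    y = site_table["hunting"].astype(float).to_numpy()
    X = site_table.loc[:, list(covariates)].astype(float)
    for c in covariates:
        if np.std(X[c].to_numpy(), ddof=1) == 0.0:
            raise ValueError(f"covariate {c!r} has zero variance")
    X = sm.add_constant(X, prepend=True)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = model.fit()
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise ValueError(
                "complete separation: the hunting flag is perfectly predicted "
                "by a covariate combination; coefficients diverge"
            ) from exc
    if np.any(np.abs(res.params) > 1e3):
        raise ValueError("complete separation suspected: diverging coefficients")
    return GlmResult(
        params=res.params,
        se=res.bse,
        z=res.tvalues,
        p=res.pvalues,
        null_deviance=float(res.null_deviance),
        deviance=float(res.deviance),
        aic=float(res.aic),
        n=int(res.nobs),
    )


@dataclass
class ContingencyResult:
    """Pearson chi-square test of independence on a contingency table."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float


def chi2_contingency(observed) -> ContingencyResult:
    """Pearson chi-square test without continuity correction.

    Expected counts come from the row/column margins; rows or columns whose
    margin is zero are dropped with a warning; a warning is also emitted
    when any expected count falls below 5 (the test is still reported, as
    is conventional in small interview samples).
    """
    obs = pd.DataFrame(observed).astype(float)
    if (obs.to_numpy() < 0).any():
        raise ValueError("contingency cells must be non-negative")
    zr = obs.sum(axis=1) == 0
    zc = obs.sum(axis=0) == 0
    if zr.any() or zc.any():
        warnings.warn(
            f"dropping zero-margin rows {list(obs.index[zr])} / "
            f"columns {list(obs.columns[zc])}",
            stacklevel=2,
        )
        obs = obs.loc[~zr, ~zc]
    chi2, p, df, expected = stats.chi2_contingency(obs.to_numpy(), correction=False)
    expected = pd.DataFrame(expected, index=obs.index, columns=obs.columns)
    if (expected.to_numpy() < 5).any():
        warnings.warn(
            "expected counts below 5; chi-square approximation is rough",
            stacklevel=2,
        )
    return ContingencyResult(
        observed=obs, expected=expected, chi2=float(chi2), df=int(df), p=float(p)
    )


def compare_lambda_by_hunting(
    lambda_predictions, hunting_flags
) -> dict[str, float]:
    """Descriptive comparison of predicted abundance at hunted vs unhunted sites.

    Returns per-group median and interquartile range plus the difference of
    medians (hunted minus unhunted).  No hypothesis test is attached.
    """
    lam = np.asarray(lambda_predictions, float)
    flags = np.asarray(hunting_flags, bool)
    if lam.shape != flags.shape:
        raise ValueError("predictions and hunting flags must align")
    out: dict[str, float] = {}
    for label, grp in (("hunted", lam[flags]), ("unhunted", lam[~flags])):
        if grp.size == 0:
            warnings.warn(f"no {label} sites in comparison", stacklevel=2)
            out[f"median_{label}"] = np.nan
            out[f"iqr_{label}"] = np.nan
        else:
            q1, q3 = np.percentile(grp, [25, 75])
            out[f"median_{label}"] = float(np.median(grp))
            out[f"iqr_{label}"] = float(q3 - q1)
    out["median_difference"] = out["median_hunted"] - out["median_unhunted"]
    return out
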