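"""Gaussian additive mixed model attributing diversity/abundance responses to
climate and herbivore predictors, with lake random intercepts.

The default model is linear in every predictor and is estimated by REML
(statsmodels ``MixedLM``).  Optional smooth terms use the mixed-model
representation of penalized regression splines: the linear part of each smooth
stays a fixed effect, the wiggly basis enters as an i.i.d. variance component,
and its variance — hence the amount of smoothing — is selected by the same
REML criterion.  Significance codes follow the t-based convention
(**** p<0.0001, *** p<0.001, ** p<0.01; two-sided, strict cutoffs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

from .tables import ValidationError

SIGNIFICANCE_CUTOFFS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"))


@dataclass
class ModelDesign:
    """A fitting problem: response, predictor table, and lake grouping."""

    response: pd.Series
    predictors: pd.DataFrame
    lake_ids: pd.Series
    smooth_terms: tuple[str, ...] = ()
    ages: pd.Series | None = None


def significance_class(p: float, cutoffs=SIGNIFICANCE_CUTOFFS) -> str:
    """Strict-inequality class for a two-sided p-value; '' above the loosest
    cutoff."""
    for cutoff, code in sorted(cutoffs):
        if p < cutoff:
            return code
    return ""


def _check_design(X: pd.DataFrame, y: np.ndarray, groups: np.ndarray) -> None:
    for col in X.columns:
        if X[col].isna().any():
            raise ValidationError(f"predictor {col!r} has missing values")
    if np.isnan(y).any():
        raise ValidationError("response has missing values")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValidationError(
            "degenerate fit: at least two lakes are required to estimate a "
            "random-intercept variance"
        )
    design = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the collinear offenders: columns whose removal restores rank
        guilty = []
        for j, col in enumerate(X.columns):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                guilty.append(col)
        raise ValidationError(f"rank-deficient design; collinear predictors: {guilty}")


def _smooth_basis(x: np.ndarray, n_splines: int) -> np.ndarray:
    """Wiggly random-effect basis of a cubic penalized spline.

    B-spline basis with a second-difference penalty, reparametrized so the
    penalized directions become i.i.d. random effects (columns scaled by
    1/sqrt(eigenvalue)); the penalty null space (constant + linear) is left to
    the fixed effects.
    """
    from statsmodels.gam.smooth_basis import BSplines

    bs = BSplines(x, df=[n_splines], degree=[3], include_intercept=True)
    B = bs.basis
    S = bs.penalty_matrices[0]
    d, U = np.linalg.eigh(S)
    pos = d > max(d.max(), 1.0) * 1e-8
    Z = B @ U[:, pos] / np.sqrt(d[pos])
    return Z


class AttributionModel(BaseEstimator):
    """Linear mixed model (optionally additive) with lake random intercepts.

    Parameters
    ----------
    smooth_terms
        Predictor names to model with a penalized cubic spline in addition to
        their linear fixed effect.
    n_splines
        Basis dimension per smooth term.
    reml
        Use restricted maximum likelihood (default) rather than ML.

    Attributes (after ``fit``)
    --------------------------
    coef_, bse_, tvalues_, pvalues_, significance_ : pandas.Series per fixed
        effect (the intercept is reported separately as ``intercept_``).
    random_intercept_var_, resid_var_ : float
    residuals_ : numpy.ndarray aligned with the fitting data.
    """

    def __init__(self, smooth_terms: tuple[str, ...] = (), n_splines: int = 8,
                 reml: bool = True):
        self.smooth_terms = tuple(smooth_terms)
        self.n_splines = n_splines
        self.reml = reml

    def fit(self, X: pd.DataFrame, y, groups):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        _check_design(X, y, groups)
        for term in self.smooth_terms:
            if term not in X.columns:
                raise ValidationError(f"smooth term {term!r} not among predictors")

        exog = pd.concat(
            [pd.Series(1.0, index=X.index, name="Intercept"), X], axis=1
        )
        self.fe_names_ = list(exog.columns)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.smooth_terms:
                result = self._fit_with_smooths(exog, y, groups)
            else:
                model = MixedLM(y, exog.to_numpy(dtype=float), groups=groups)
                result = model.fit(reml=self.reml)

        self.result_ = result
        self._boundary_ols_ = (
            not self.smooth_terms and self._extract_intercept_var(result) <= 0.0
        )
        if self._boundary_ols_:
            # REML put the random-intercept variance on the zero boundary; the
            # model degenerates to OLS, and statsmodels' singular-covariance
            # path returns unreliable fixed effects, so solve OLS directly.
            return self._finish_as_ols(exog, y, groups)
        params = np.asarray(result.fe_params)[: len(self.fe_names_)]
        bse = np.asarray(result.bse_fe)[: len(self.fe_names_)]
        names = self.fe_names_
        self.intercept_ = float(params[0])
        self.coef_ = pd.Series(params[1:], index=names[1:])
        self.bse_ = pd.Series(bse[1:], index=names[1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = self.coef_ / self.bse_
        self.tvalues_ = tvals
        df = max(len(y) - len(names), 1)
        self.df_resid_ = df
        self.pvalues_ = pd.Series(
            2.0 * stats.t.sf(np.abs(tvals.to_numpy()), df), index=tvals.index
        )
        self.significance_ = self.pvalues_.map(significance_class)
        self.resid_var_ = float(result.scale)
        self.random_intercept_var_ = self._extract_intercept_var(result)
        try:
            fitted = np.asarray(result.fittedvalues, dtype=float)
        except (ValueError, np.linalg.LinAlgError):
            # variance component at the boundary: BLUPs are all zero
            fitted = exog.to_numpy(dtype=float) @ np.asarray(result.fe_params)
        self.residuals_ = y - fitted
        self.n_obs_ = len(y)
        self._groups = groups
        return self

    # -- internals ---------------------------------------------------------

    def _finish_as_ols(self, exog: pd.DataFrame, y, groups):
        X = exog.to_numpy(dtype=float)
        params, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ params
        df = max(len(y) - X.shape[1], 1)
        s2 = float(resid @ resid) / df
        cov = s2 * np.linalg.inv(X.T @ X)
        bse = np.sqrt(np.diag(cov))
        names = self.fe_names_
        self.intercept_ = float(params[0])
        self.coef_ = pd.Series(params[1:], index=names[1:])
        self.bse_ = pd.Series(bse[1:], index=names[1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            self.tvalues_ = self.coef_ / self.bse_
        self.df_resid_ = df
        self.pvalues_ = pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues_.to_numpy()), df),
            index=self.tvalues_.index,
        )
        self.significance_ = self.pvalues_.map(significance_class)
        self.resid_var_ = s2
        self.random_intercept_var_ = 0.0
        self.residuals_ = resid
        self.n_obs_ = len(y)
        self._groups = groups
        return self

    def _fit_with_smooths(self, exog: pd.DataFrame, y, groups):
        # single umbrella group: lake intercepts and each smooth's wiggly
        # basis all become variance components, so REML selects the smoothing
        lakes = pd.Categorical(groups)
        lake_dummies = pd.get_dummies(pd.Series(lakes)).to_numpy(dtype=float)
        names = ["lake"]
        mats = [[lake_dummies]]
        for term in self.smooth_terms:
            x = exog[term].to_numpy(dtype=float)
            names.append(f"s({term})")
            mats.append([_smooth_basis(x, self.n_splines)])
        colnames = [
            [[f"{name}[{j}]" for j in range(group_mats[0].shape[1])]]
            for name, group_mats in zip(names, mats)
        ]
        umbrella = np.zeros(len(y), dtype=int)
        model = MixedLM(
            y,
            exog.to_numpy(dtype=float),
            groups=umbrella,
            exog_re=None,
            exog_vc=VCSpec(names, colnames, mats),
        )
        return model.fit(reml=self.reml)

    def _extract_intercept_var(self, result) -> float:
        if self.smooth_terms:
            names = list(result.model.exog_vc.names)
            return float(np.asarray(result.vcomp)[names.index("lake")])
        cov_re = np.asarray(result.cov_re)
        return float(cov_re[0, 0]) if cov_re.size else 0.0

    def predict(self, X: pd.DataFrame, groups=None) -> np.ndarray:
        """Fixed-effect prediction, plus the estimated lake intercept when the
        model was fit without smooths and ``groups`` are supplied."""
        X = pd.DataFrame(X)
        out = self.intercept_ + X[self.coef_.index].to_numpy(dtype=float) @ \
            self.coef_.to_numpy()
        if (
            groups is not None
            and not self.smooth_terms
            and not getattr(self, "_boundary_ols_", False)
        ):
            re = {
                k: float(np.asarray(v)[0]) for k, v in
                self.result_.random_effects.items()
            }
            out = out + np.array([re.get(g, 0.0) for g in np.asarray(groups)])
        return out

    def summary_frame(self) -> pd.DataFrame:
        """Per-predictor coefficients, SEs, t-values, p-values and codes."""
        return pd.DataFrame(
            {
                "coefficient": self.coef_,
                "std_error": self.bse_,
                "t_value": self.tvalues_,
                "p_value": self.pvalues_,
                "significance": self.significance_,
            }
        )


def fit_attribution(design: ModelDesign) -> AttributionModel:
    """Fit the attribution model described by a :class:`ModelDesign`."""
    model = AttributionModel(smooth_terms=design.smooth_terms)
    return model.fit(design.predictors, design.response, design.lake_ids)


def significance_classes(model: AttributionModel) -> pd.Series:
    return model.significance_.copy()


def check_autocorrelation(
    residuals,
    lake_ids,
    ages,
    alpha: float = 0.05,
    min_samples: int = 3,
) -> tuple[pd.DataFrame, str]:
    """Per-lake lag-1 autocorrelation of age-ordered residuals.

    Each lake's residual series (ordered old → young) yields a lag-1
    autocorrelation and a Durbin–Watson statistic.  A lake is flagged when
    |lag-1| exceeds the Bonferroni-adjusted normal critical value
    z(1 - alpha / (2 m)) / sqrt(n).  The verdict is "no evidence" when no lake
    is flagged, otherwise "autocorrelation detected".  Lakes with fewer than
    ``min_samples`` samples are skipped with a note.
    """
    df = pd.DataFrame(
        {
            "resid": np.asarray(residuals, dtype=float),
            "lake_id": np.asarray(lake_ids),
            "age_ka": np.asarray(ages, dtype=float),
        }
    )
    testable = [g for _, g in df.groupby("lake_id") if len(g) >= min_samples]
    m = max(len(testable), 1)
    z_crit = stats.norm.ppf(1 - alpha / (2 * m))
    rows = []
    for lake, g in df.groupby("lake_id"):
        if len(g) < min_samples:
            rows.append(
                {
                    "lake_id": lake,
                    "n": len(g),
                    "lag1": np.nan,
                    "durbin_watson": np.nan,
                    "flagged": False,
                    "note": f"skipped: fewer than {min_samples} samples",
                }
            )
            continue
        r = g.sort_values("age_ka")["resid"].to_numpy()
        r = r - r.mean()
        denom = float(r @ r)
        lag1 = float(r[1:] @ r[:-1]) / denom if denom > 0 else 0.0
        dw = float(np.sum(np.diff(r) ** 2)) / denom if denom > 0 else 2.0
        flagged = abs(lag1) > z_crit / np.sqrt(len(r))
        rows.append(
            {
                "lake_id": lake,
                "n": len(g),
                "lag1": lag1,
                "durbin_watson": dw,
                "flagged": bool(flagged),
                "note": "",
            }
        )
    table = pd.DataFrame(rows)
    verdict = (
        "autocorrelation detected" if table["flagged"].any() else "no evidence"
    )
    return table, verdict
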