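"""Nested demographic growth and survival models with neighbourhood effects.

Growth of a focal tree is modelled multiplicatively,

    Growth = G_i * DBH**gamma * exp(Pair) * exp(HOI),

and fitted by ordinary least squares after log transformation. Survival over
the census interval is a logistic regression on a flexible size profile
(1/DBH, DBH, DBH^2) plus the same neighbourhood terms, parameterized so that
a negative interaction coefficient lowers survival probability.

Three nested classes are fitted per species: ``null`` (size only),
``pair_only`` (adds the conspecific and heterospecific pairwise crowding
indices n_i, n_h) and ``hoi`` (adds the four higher-order indices). Pairwise
coefficients from the pair-only model absorb any higher-order effects
(alpha_modified); those from the HOI-inclusive model isolate them
(alpha_true). A model class is "supported" only when its AIC undercuts every
simpler class by at least two units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

MODEL_CLASSES = ("null", "pair_only", "hoi")

PAIR_TERMS = ["n_i", "n_h"]
HOI_TERMS = ["n_ii", "n_ih", "n_hi", "n_hh"]

#: Friendly coefficient names used in output tables.
COEF_NAMES = {
    "n_i": "alpha_ii",
    "n_h": "alpha_ih",
    "n_ii": "beta_iii",
    "n_ih": "beta_iih",
    "n_hi": "beta_ihi",
    "n_hh": "beta_ihh",
}


@dataclass
class SpeciesModelFit:
    """One fitted demographic model for one species in one plot.

    ``params``/``bse`` are keyed by design-column name (``const``,
    ``log_dbh`` or the survival size terms, then crowding indices). ``aic``
    is ``-2 loglik + 2k`` with k counting every free parameter, including
    the Gaussian variance for growth fits. ``dropped`` lists design columns
    removed because they were constant (degenerate designs complete with a
    flag instead of failing).
    """

    species: str
    plot_id: str
    response: str
    model_class: str
    params: dict[str, float]
    bse: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    aic: float
    loglik: float
    n_obs: int
    dropped: list[str] = field(default_factory=list)
    ridge_fallback: bool = False
    _design_columns: list[str] = field(default_factory=list, repr=False)

    @property
    def degenerate(self) -> bool:
        return bool(self.dropped)

    def coefficient(self, index_name: str) -> float:
        """Coefficient on a crowding index, NaN if not in this model class."""
        return self.params.get(index_name, float("nan"))

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        X = _design(data, self.response, self.model_class)
        eta = np.zeros(len(X))
        for c in self._design_columns:
            eta += self.params[c] * X[c].to_numpy(float)
        return eta

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Predicted log-growth (growth) or survival probability (survival)."""
        eta = self.linear_predictor(data)
        if self.response == "growth":
            return eta
        return 1.0 / (1.0 + np.exp(-eta))


def _design(data: pd.DataFrame, response: str, model_class: str) -> pd.DataFrame:
    if model_class not in MODEL_CLASSES:
        raise ValueError(f"unknown model class {model_class!r}")
    dbh = data["dbh0"].to_numpy(float)
    if response == "growth":
        X = pd.DataFrame({"const": 1.0, "log_dbh": np.log(dbh)}, index=data.index)
    elif response == "survival":
        X = pd.DataFrame(
            {"const": 1.0, "inv_dbh": 1.0 / dbh, "dbh": dbh, "dbh_sq": dbh**2},
            index=data.index,
        )
    else:
        raise ValueError(f"unknown response {response!r}")
    if model_class in ("pair_only", "hoi"):
        for c in PAIR_TERMS:
            X[c] = data[c].to_numpy(float)
    if model_class == "hoi":
        for c in HOI_TERMS:
            X[c] = data[c].to_numpy(float)
    return X


def _drop_degenerate(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    dropped = [
        c for c in X.columns if c != "const" and float(np.ptp(X[c].to_numpy())) == 0.0
    ]
    if dropped:
        logger.warning("dropping constant design columns: %s", dropped)
    return X.drop(columns=dropped), dropped


def fit_growth(
    data: pd.DataFrame,
    model_class: str,
    *,
    species: str = "",
    plot_id: str = "",
) -> SpeciesModelFit:
    """Fit one growth model class by OLS on log growth.

    `data` holds one row per eligible focal tree (surviving, interior,
    species passing the abundance filter) with columns ``growth``, ``dbh0``
    and the crowding indices. The response is ``log(growth)``; growth must be
    strictly positive (non-positive increments are floored upstream).
    """
    if (data["growth"] <= 0).any() or data["growth"].isna().any():
        raise ValueError("growth must be positive and non-missing (apply floor upstream)")
    y = np.log(data["growth"].to_numpy(float))
    X, dropped = _drop_degenerate(_design(data, "growth", model_class))
    res = sm.OLS(y, X).fit()
    k = res.df_model + 1 + 1  # slopes + intercept + Gaussian variance
    ci = res.conf_int()
    return SpeciesModelFit(
        species=species,
        plot_id=plot_id,
        response="growth",
        model_class=model_class,
        params=dict(res.params),
        bse=dict(res.bse),
        conf_int={c: (float(ci.loc[c, 0]), float(ci.loc[c, 1])) for c in X.columns},
        aic=float(-2 * res.llf + 2 * k),
        loglik=float(res.llf),
        n_obs=int(res.nobs),
        dropped=dropped,
        _design_columns=list(X.columns),
    )


def fit_survival(
    data: pd.DataFrame,
    model_class: str,
    *,
    species: str = "",
    plot_id: str = "",
    ridge_alpha: float = 1e-4,
) -> SpeciesModelFit:
    """Fit one survival model class by maximum-likelihood logistic regression.

    The linear predictor eta enters as P(survive) = 1 / (1 + exp(-eta)), so
    a negative crowding coefficient lowers survival. On perfect separation or
    non-convergence the fit falls back to a lightly ridge-penalized logistic
    fit (flagged on the result) so batch runs complete.
    """
    y = data["survived"].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("survival outcomes are all identical; species fails filters")
    X, dropped = _drop_degenerate(_design(data, "survival", model_class))
    ridge = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            ok = np.isfinite(res.bse.to_numpy()).all() and res.mle_retvals.get(
                "converged", True
            )
        except Exception:
            ok = False
        if not ok:
            ridge = True
            logger.warning("survival fit for %s: ridge fallback (separation?)", species)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                alpha=ridge_alpha, L1_wt=0.0
            )
    k = X.shape[1]
    params = dict(zip(X.columns, np.atleast_1d(np.asarray(res.params, float))))
    if ridge:
        eta = np.asarray(X @ np.asarray(res.params, float), float)
        p = np.clip(1 / (1 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        llf = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        bse = {c: float("nan") for c in X.columns}
        ci = {c: (float("nan"), float("nan")) for c in X.columns}
    else:
        llf = float(res.llf)
        bse = dict(res.bse)
        cidf = res.conf_int()
        ci = {c: (float(cidf.loc[c, 0]), float(cidf.loc[c, 1])) for c in X.columns}
    return SpeciesModelFit(
        species=species,
        plot_id=plot_id,
        response="survival",
        model_class=model_class,
        params=params,
        bse=bse,
        conf_int=ci,
        aic=float(-2 * llf + 2 * k),
        loglik=llf,
        n_obs=len(y),
        dropped=dropped,
        ridge_fallback=ridge,
        _design_columns=list(X.columns),
    )


def fit_all_classes(
    data: pd.DataFrame, response: str, *, species: str = "", plot_id: str = ""
) -> dict[str, SpeciesModelFit]:
    """Fit the null, pair-only and HOI-inclusive models for one species."""
    fitter = fit_growth if response == "growth" else fit_survival
    return {
        mc: fitter(data, mc, species=species, plot_id=plot_id) for mc in MODEL_CLASSES
    }


@dataclass(frozen=True)
class ModelSupport:
    """AIC-based support classification for one species x plot x response."""

    species: str
    plot_id: str
    response: str
    best: str
    delta_aic_to_simpler: float


def classify_support(
    aic_null: float,
    aic_pair: float,
    aic_hoi: float,
    *,
    species: str = "",
    plot_id: str = "",
    response: str = "",
    threshold: float = 2.0,
) -> ModelSupport:
    """Apply the delta-AIC >= 2 support rule to three nested model AICs.

    The HOI-inclusive model is supported only when its AIC is at least
    `threshold` units below both simpler models; otherwise the pair-only
    model is supported when it undercuts the null by `threshold`; otherwise
    the null stands (within-threshold ties collapse to the simplest model).
    """
    for a in (aic_null, aic_pair, aic_hoi):
        if not np.isfinite(a):
            raise ValueError("all three AICs must be finite")
    if aic_hoi <= min(aic_null, aic_pair) - threshold:
        best, delta = "hoi", min(aic_null, aic_pair) - aic_hoi
    elif aic_pair <= aic_null - threshold:
        best, delta = "pair_only", aic_null - aic_pair
    else:
        best, delta = "null", aic_null - min(aic_pair, aic_hoi)
    return ModelSupport(species, plot_id, response, best, float(delta))


def support_summary(supports: list[ModelSupport]) -> dict[str, float]:
    """Percentage of species-plot combinations best supporting each class."""
    if not supports:
        raise ValueError("no support records")
    n = len(supports)
    return {
        mc: 100.0 * sum(s.best == mc for s in supports) / n for mc in MODEL_CLASSES
    }


def predicted_observed_correlation(
    fits: dict[str, SpeciesModelFit], data: pd.DataFrame
) -> dict[str, float]:
    """In-sample Pearson r between observed and predicted response per class.

    For growth the comparison is on the log scale (observed log growth vs the
    fitted linear predictor); for survival it is the 0/1 outcome vs the
    predicted survival probability.
    """
    if any(f.response == "growth" for f in fits.values()):
        obs = np.log(data["growth"].to_numpy(float))
    else:
        obs = data["survived"].to_numpy(float)
    out = {}
    for mc, fit in fits.items():
        pred = fit.predict(data)
        out[mc] = float(np.corrcoef(obs, pred)[0, 1]) if np.ptp(pred) > 0 else 0.0
    return out


def compare_correlations(per_species: pd.DataFrame) -> pd.DataFrame:
    """Paired two-sided t-tests of predictive correlations between classes.

    `per_species` has one row per species and one column of Pearson r per
    model class. Returns a tidy frame of pairwise comparisons.
    """
    rows = []
    classes = [c for c in MODEL_CLASSES if c in per_species.columns]
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            t, p = stats.ttest_rel(per_species[b], per_species[a])
            rows.append(
                {
                    "better": b,
                    "worse": a,
                    "mean_diff": float((per_species[b] - per_species[a]).mean()),
                    "t": float(t),
                    "p_value": float(p),
                    "n": len(per_species),
                }
            )
    return pd.DataFrame(rows)
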