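"""Latitudinal gradients in interaction coefficients and species richness.

Species-level interaction coefficients are related to absolute latitude with
exponential models, fitted separately for competitive (coefficient < 0) and
facilitative (coefficient > 0) subsets: the magnitude model
``|coef| = a * exp(b * |lat|)`` becomes OLS of ``log|coef|`` on latitude, and
the slope's two-sided t-test measures whether interaction strength changes
with latitude. Plot richness follows the same exponential treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

SIGN_SUBSETS = ("competitive", "facilitative")


@dataclass(frozen=True)
class GradientFit:
    """Exponential latitude regression for one coefficient type x sign subset.

    ``slope`` is the per-degree exponential rate on the magnitude scale
    (negative slope = interactions weaken polewards); ``log_intercept`` is
    the log magnitude at the equator. ``reason`` is set (and statistics are
    NaN) when no fit could be made, e.g. an empty sign subset or n < 3.
    """

    coefficient_type: str
    sign_subset: str
    log_intercept: float
    slope: float
    t_stat: float
    p_value: float
    n: int
    reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.reason is None


def _no_fit(coefficient_type: str, sign_subset: str, n: int, reason: str) -> GradientFit:
    nan = float("nan")
    return GradientFit(coefficient_type, sign_subset, nan, nan, nan, nan, n, reason)


def exponential_latitude_fit(
    values,
    latitudes,
    sign_subset: str,
    coefficient_type: str = "",
    min_n: int = 3,
) -> GradientFit:
    """Fit ``log|value| ~ |latitude|`` on one sign subset of coefficients.

    `values` are signed species-level coefficients; the competitive subset
    keeps strictly negative values, the facilitative subset strictly positive
    ones, and zeros enter neither. The slope's significance is a two-sided
    t-test with n - 2 degrees of freedom.
    """
    if sign_subset not in SIGN_SUBSETS:
        raise ValueError(f"sign_subset must be one of {SIGN_SUBSETS}")
    v = np.asarray(values, float)
    lat = np.abs(np.asarray(latitudes, float))
    keep = (v < 0) if sign_subset == "competitive" else (v > 0)
    keep &= np.isfinite(v) & np.isfinite(lat)
    if keep.sum() < min_n:
        return _no_fit(coefficient_type, sign_subset, int(keep.sum()),
                       f"fewer than {min_n} values in subset")
    y = np.log(np.abs(v[keep]))
    if np.ptp(y) == 0.0:  # constant magnitudes: flat gradient, no evidence of trend
        return GradientFit(coefficient_type, sign_subset, float(y[0]), 0.0, 0.0, 1.0,
                           int(keep.sum()))
    X = sm.add_constant(lat[keep])
    res = sm.OLS(y, X).fit()
    if len(res.params) < 2:  # constant latitude: slope unidentifiable
        return _no_fit(coefficient_type, sign_subset, int(keep.sum()),
                       "latitude constant across values")
    return GradientFit(
        coefficient_type=coefficient_type,
        sign_subset=sign_subset,
        log_intercept=float(res.params[0]),
        slope=float(res.params[1]),
        t_stat=float(res.tvalues[1]),
        p_value=float(res.pvalues[1]),
        n=int(keep.sum()),
    )


def richness_gradient(richness, latitudes) -> GradientFit:
    """Exponential regression of plot species richness on absolute latitude.

    ``log(richness) ~ |lat|`` by OLS with one value per plot; the slope's
    t statistic uses n - 2 degrees of freedom.
    """
    r = np.asarray(richness, float)
    lat = np.abs(np.asarray(latitudes, float))
    if np.any(r <= 0):
        raise ValueError("richness values must be positive")
    if len(r) == 2 and lat[0] != lat[1]:
        # two plots determine a slope exactly but admit no significance test
        slope = float((np.log(r[1]) - np.log(r[0])) / (lat[1] - lat[0]))
        return GradientFit("richness", "n/a", float(np.log(r[0]) - slope * lat[0]),
                           slope, float("nan"), float("nan"), 2,
                           "two plots: slope only, no significance test")
    if len(r) < 3:
        return _no_fit("richness", "n/a", len(r), "need at least 3 plots")
    if np.ptp(np.log(r)) == 0.0:
        return GradientFit("richness", "n/a", float(np.log(r[0])), 0.0, 0.0, 1.0, len(r))
    res = sm.OLS(np.log(r), sm.add_constant(lat)).fit()
    if len(res.params) < 2:
        return _no_fit("richness", "n/a", len(r), "latitude constant across plots")
    return GradientFit(
        coefficient_type="richness",
        sign_subset="n/a",
        log_intercept=float(res.params[0]),
        slope=float(res.params[1]),
        t_stat=float(res.tvalues[1]),
        p_value=float(res.pvalues[1]),
        n=len(r),
    )


def quadrat_richness(stems: pd.DataFrame, x_extent: float, y_extent: float,
                     quadrat: float = 100.0) -> float:
    """Species richness per hectare: mean species count over non-overlapping
    ``quadrat x quadrat`` m quadrats (default 100 m, i.e. 1 ha)."""
    nx = max(1, int(x_extent // quadrat))
    ny = max(1, int(y_extent // quadrat))
    qx = np.clip((stems["gx"].to_numpy(float) // quadrat).astype(int), 0, nx - 1)
    qy = np.clip((stems["gy"].to_numpy(float) // quadrat).astype(int), 0, ny - 1)
    counts = (
        pd.DataFrame({"q": qx * ny + qy, "sp": stems["sp"].to_numpy()})
        .groupby("q")["sp"].nunique()
    )
    full = counts.reindex(range(nx * ny), fill_value=0)
    return float(full.mean())


def alpha_beta_correlation(coeffs: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between true pairwise and higher-order coefficients.

    `coeffs` holds one row per species with HOI-inclusive model estimates in
    columns ``alpha_ii, alpha_ih, beta_iih, beta_ihh`` (and optionally the
    other beta columns). Returns r and p for the (alpha_ii, beta_iih) and
    (alpha_ih, beta_ihh) pairs — the channels through which heterospecific
    initiators modify intra- and interspecific pairwise effects.
    """
    pairs = [("alpha_ii", "beta_iih"), ("alpha_ih", "beta_ihh")]
    rows = []
    for a, b in pairs:
        sub = coeffs[[a, b]].dropna()
        if len(sub) < 3:
            rows.append({"pair": f"{a}~{b}", "r": float("nan"),
                         "p_value": float("nan"), "n": len(sub)})
            continue
        r, p = stats.pearsonr(sub[a], sub[b])
        rows.append({"pair": f"{a}~{b}", "r": float(r), "p_value": float(p),
                     "n": len(sub)})
    return pd.DataFrame(rows)


def plot_level_summary(coeffs: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    """Per-plot mean and s.e.m. of species-level coefficients by sign subset.

    One output row per plot x coefficient x sign subset; the s.e.m. is NaN
    (flagged ``single_species``) when only one species enters the cell.
    """
    rows = []
    for col in value_cols:
        sub = coeffs[["plot_id", "latitude", col]].dropna()
        for subset in SIGN_SUBSETS:
            mask = sub[col] < 0 if subset == "competitive" else sub[col] > 0
            g = sub[mask].groupby(["plot_id", "latitude"])[col]
            agg = g.agg(["mean", "sem", "count"]).reset_index()
            for _, r in agg.iterrows():
                rows.append(
                    {
                        "plot_id": r["plot_id"],
                        "latitude": r["latitude"],
                        "coefficient_type": col,
                        "sign_subset": subset,
                        "mean": float(r["mean"]),
                        "sem": float(r["sem"]) if r["count"] > 1 else float("nan"),
                        "n_species": int(r["count"]),
                        "single_species": bool(r["count"] == 1),
                    }
                )
    return pd.DataFrame(rows)
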