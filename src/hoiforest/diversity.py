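"""Cumulative neighbourhood effects and their link to the diversity gradient.

For each focal tree the fitted HOI-inclusive model decomposes the
multiplicative neighbourhood effect on growth into a pairwise factor
``exp(Pair)`` and a higher-order factor ``exp(HOI)``. Averaging each factor
over a species' trees gives the species-level relative changes RC_Pair and
RC_HOI: multipliers > 1 mean the neighbourhood on balance boosts performance,
< 1 that it suppresses it. Regressing log RC on log abundance, absolute
latitude and their interaction tests whether the effects are stabilizing
(negative abundance slope: rare species benefit, common species suffer) and
whether that stabilization weakens polewards (positive interaction term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .models import HOI_TERMS, PAIR_TERMS, SpeciesModelFit

ZONE_MID_LATITUDES = {"tropical": 11.75, "subtropical": 29.25, "temperate": 45.0}


@dataclass(frozen=True)
class RCRecord:
    """Species-level cumulative-effect multipliers.

    ``rc_pair``/``rc_hoi`` are the species means of ``exp(Pair)`` and
    ``exp(HOI)`` over focal trees — dimensionless multipliers on growth rate
    (or the survival linear predictor). ``abundance`` is stems per hectare.
    """

    species: str
    plot_id: str
    rc_pair: float
    rc_hoi: float
    abundance: float
    latitude_abs: float
    n_trees: int


def tree_level_effects(fit: SpeciesModelFit, profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-tree Pair and HOI linear effects under an HOI-inclusive fit."""
    if fit.model_class != "hoi":
        raise ValueError("cumulative effects require an HOI-inclusive fit")
    pair = np.zeros(len(profiles))
    hoi = np.zeros(len(profiles))
    for c in PAIR_TERMS:
        pair += fit.params.get(c, 0.0) * profiles[c].to_numpy(float)
    for c in HOI_TERMS:
        hoi += fit.params.get(c, 0.0) * profiles[c].to_numpy(float)
    return pd.DataFrame({"pair_effect": pair, "hoi_effect": hoi}, index=profiles.index)


def compute_rc(
    fit: SpeciesModelFit,
    profiles: pd.DataFrame,
    *,
    abundance: float,
    latitude: float,
) -> RCRecord:
    """Species-level RC_Pair and RC_HOI from one HOI-inclusive fit.

    `profiles` holds the interior crowding profiles of the species' focal
    trees. Each tree contributes ``exp(Pair)`` and ``exp(HOI)``; the record
    stores their means. A species whose trees all have zero crowding yields
    the neutral multipliers (1, 1).
    """
    eff = tree_level_effects(fit, profiles)
    return RCRecord(
        species=fit.species,
        plot_id=fit.plot_id,
        rc_pair=float(np.exp(eff["pair_effect"]).mean()),
        rc_hoi=float(np.exp(eff["hoi_effect"]).mean()),
        abundance=float(abundance),
        latitude_abs=float(abs(latitude)),
        n_trees=len(profiles),
    )


def rc_records_frame(records: list[RCRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sp": r.species,
                "plot_id": r.plot_id,
                "rc_pair": r.rc_pair,
                "rc_hoi": r.rc_hoi,
                "abundance": r.abundance,
                "latitude_abs": r.latitude_abs,
                "n_trees": r.n_trees,
            }
            for r in records
        ]
    )


def rc_abundance_latitude_model(records: pd.DataFrame, response: str = "rc_hoi"):
    """OLS of log RC on log abundance, absolute latitude and their interaction.

    Returns the fitted statsmodels results; design columns are ``const``,
    ``log_abundance``, ``latitude_abs`` and ``abundance_latitude``. Natural
    logarithms are used throughout.
    """
    if response not in ("rc_pair", "rc_hoi"):
        raise ValueError("response must be 'rc_pair' or 'rc_hoi'")
    if len(records) < 4:
        raise ValueError("need at least 4 species to fit the 4-term model")
    la = np.log(records["abundance"].to_numpy(float))
    lat = np.abs(records["latitude_abs"].to_numpy(float))
    X = pd.DataFrame(
        {
            "const": 1.0,
            "log_abundance": la,
            "latitude_abs": lat,
            "abundance_latitude": la * lat,
        },
        index=records.index,
    )
    y = np.log(records[response].to_numpy(float))
    return sm.OLS(y, X).fit()


def rc_model_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-term summary of the RC models for both responses."""
    rows = []
    for response in ("rc_pair", "rc_hoi"):
        res = rc_abundance_latitude_model(records, response)
        for term in res.params.index:
            rows.append(
                {
                    "response": response,
                    "term": term,
                    "estimate": float(res.params[term]),
                    "se": float(res.bse[term]),
                    "t": float(res.tvalues[term]),
                    "p_value": float(res.pvalues[term]),
                    "n": int(res.nobs),
                }
            )
    return pd.DataFrame(rows)


def zone_predictions(
    model,
    abundance_grid,
    latitudes: dict[str, float] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Predicted log RC vs log abundance at zone mid-latitudes with 95% CI.

    `model` is a fit from :func:`rc_abundance_latitude_model`; `latitudes`
    defaults to the tropical / subtropical / temperate zone midpoints
    (11.75, 29.25 and 45 degrees). Confidence bands are pointwise.
    """
    latitudes = latitudes or ZONE_MID_LATITUDES
    la = np.log(np.asarray(abundance_grid, float))
    frames = []
    for zone, lat in latitudes.items():
        X = pd.DataFrame(
            {
                "const": 1.0,
                "log_abundance": la,
                "latitude_abs": float(lat),
                "abundance_latitude": la * float(lat),
            }
        )
        pred = model.get_prediction(X).summary_frame(alpha=alpha)
        frames.append(
            pd.DataFrame(
                {
                    "zone": zone,
                    "latitude": float(lat),
                    "log_abundance": la,
                    "predicted": pred["mean"].to_numpy(),
                    "ci_low": pred["mean_ci_lower"].to_numpy(),
                    "ci_high": pred["mean_ci_upper"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
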