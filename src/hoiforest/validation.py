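"""Replicate validation studies: oracle equivalence, parameter recovery,
AIC support behaviour, gradient and RC recovery.

These studies define the package's self-checks under known truth. They use a
fixed spatial design per study (one simulated stem map) and redraw the
stochastic demography per replicate: conditional on the design, the OLS and
logistic interval coverage being probed is exactly the textbook property, and
replicates stay cheap enough to run routinely. All randomness flows from the
single seed argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gradients import exponential_latitude_fit
from .models import fit_all_classes, fit_growth, fit_survival
from .neighborhood import (
    CrowdingConfig,
    compute_crowding_table,
    higher_order_indices,
    pairwise_indices,
)
from .simulate import SimConfig, simulate_truth_network

GROWTH_COEFS = ["const", "log_dbh", "n_i", "n_h", "n_ii", "n_ih", "n_hi", "n_hh"]
SURVIVAL_COEFS = ["const", "inv_dbh", "dbh", "dbh_sq", "n_i", "n_h", "n_ii", "n_ih", "n_hi", "n_hh"]

#: Well-identified interaction strengths used by the recovery studies,
#: scaled to the typical index magnitudes of the study design below.
GROWTH_TRUTH = {
    "const": float(np.log(0.2)),
    "log_dbh": 0.4,
    "n_i": -0.02,
    "n_h": 0.01,
    "n_ii": -1e-3,
    "n_ih": 5e-4,
    "n_hi": -5e-4,
    "n_hh": 2e-4,
}
SURVIVAL_TRUTH = {
    "const": 2.0,
    "inv_dbh": -0.8,
    "dbh": 0.02,
    "dbh_sq": -2e-4,
    "n_i": -0.02,
    "n_h": 0.01,
    "n_ii": -1e-3,
    "n_ih": 5e-4,
    "n_hi": -5e-4,
    "n_hh": 2e-4,
}


def reference_crowding_table(
    stems: pd.DataFrame, x_extent: float, y_extent: float, cfg: CrowdingConfig
) -> pd.DataFrame:
    """Exhaustive per-focal crowding computation (no spatial indexing).

    Loops over every focal stem and evaluates the pairwise and higher-order
    index definitions directly over all stem pairs and transmitter
    neighbourhoods; serves as the independent oracle for the accelerated
    :func:`~hoiforest.neighborhood.compute_crowding_table`.
    """
    x = stems["gx"].to_numpy(float)
    y = stems["gy"].to_numpy(float)
    dbh = stems["dbh"].to_numpy(float)
    sp = stems["sp"].to_numpy()
    rows = []
    margin = 2 * cfg.radius
    for f in range(len(stems)):
        n_i, n_h = pairwise_indices(f, x, y, dbh, sp, cfg)
        n_ii, n_ih, n_hi, n_hh = higher_order_indices(f, x, y, dbh, sp, cfg)
        rows.append(
            {
                "sp": sp[f],
                "n_i": n_i,
                "n_h": n_h,
                "n_ii": n_ii,
                "n_ih": n_ih,
                "n_hi": n_hi,
                "n_hh": n_hh,
                "interior": bool(
                    margin <= x[f] <= x_extent - margin
                    and margin <= y[f] <= y_extent - margin
                ),
            }
        )
    return pd.DataFrame(rows)


def random_stem_map(rng: np.random.Generator, n: int, extent: float, n_species: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "treeID": [f"t{i}" for i in range(n)],
            "stemID": ["1"] * n,
            "sp": rng.choice([f"s{k}" for k in range(n_species)], size=n),
            "gx": rng.uniform(0, extent, n),
            "gy": rng.uniform(0, extent, n),
            "dbh": rng.lognormal(np.log(3), 0.8, n) + 1.0,
        }
    )


def crowding_equivalence_study(
    seed: int, n_plots: int = 50, max_stems: int = 2000, extent: float = 60.0
) -> dict:
    """Max relative disagreement between accelerated and exhaustive indices.

    Generates `n_plots` random stem maps (sizes log-uniform up to
    `max_stems`, 1-5 species, varied kernel exponents) and compares all six
    indices between the two computation paths.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    total = 0
    # 49 small varied plots plus one larger instance on the default kernel
    sizes = [
        int(np.exp(rng.uniform(np.log(30), np.log(320)))) for _ in range(n_plots - 1)
    ] + [min(max_stems, 1000)]
    for k, n in enumerate(sizes):
        last = k == len(sizes) - 1
        cfg = CrowdingConfig(
            radius=8.0 if last else float(rng.uniform(5, 15)),
            size_exponent=1.0 if last else float(rng.choice([1.0, 2.0])),
            distance_exponent=1.0 if last else float(rng.choice([1.0, 2.0])),
            exclude_focal_from_neighbor_crowding=bool(last or rng.random() < 0.8),
        )
        plot_extent = 100.0 if last else extent
        stems = random_stem_map(rng, n, plot_extent, int(rng.integers(1, 6)))
        extent_here = plot_extent
        fast = compute_crowding_table(stems, extent_here, extent_here, cfg).sort_index()
        ref = reference_crowding_table(stems, extent_here, extent_here, cfg)
        for col in ("n_i", "n_h", "n_ii", "n_ih", "n_hi", "n_hh"):
            a = fast[col].to_numpy()
            b = ref[col].to_numpy()
            rel = np.abs(a - b) / np.maximum(np.maximum(np.abs(a), np.abs(b)), 1.0)
            worst = max(worst, float(rel.max()))
        assert (fast["interior"].to_numpy() == ref["interior"].to_numpy()).all()
        total += n
    return {"max_rel_error": worst, "n_plots": n_plots, "n_stems": total}


def single_species_design(
    seed,
    n_focal: int = 2000,
    extent: float = 300.0,
    density: float = 0.12,
    focal_fraction: float = 0.3,
    n_background_species: int = 5,
    cfg: CrowdingConfig | None = None,
) -> pd.DataFrame:
    """A fixed stem map with one focal species, profiled and filtered.

    Returns a design frame of exactly `n_focal` interior focal stems with
    columns ``dbh0`` and the six crowding indices, ready for the recovery
    studies. The layout is uniform-random with shifted-lognormal DBHs
    (all above the 1 cm census minimum).
    """
    rng = np.random.default_rng(seed)
    cfg = cfg or CrowdingConfig()
    n = int(density * extent * extent)
    labels = ["focal"] + [f"bg{k}" for k in range(n_background_species)]
    probs = [focal_fraction] + [(1 - focal_fraction) / n_background_species] * n_background_species
    stems = pd.DataFrame(
        {
            "treeID": [f"t{i}" for i in range(n)],
            "stemID": ["1"] * n,
            "sp": rng.choice(labels, size=n, p=probs),
            "gx": rng.uniform(0, extent, n),
            "gy": rng.uniform(0, extent, n),
            "dbh": rng.lognormal(np.log(3), 0.8, n) + 1.0,
        }
    )
    prof = compute_crowding_table(stems, extent, extent, cfg, species=["focal"])
    prof = prof[prof["interior"]]
    if len(prof) < n_focal:
        raise ValueError(f"design yielded only {len(prof)} interior focal stems")
    prof = prof.iloc[:n_focal].copy()
    prof["dbh0"] = stems["dbh"].to_numpy()[prof.index]
    return prof.reset_index(drop=True)


def _growth_response(design: pd.DataFrame, truth: dict[str, float]) -> np.ndarray:
    eta = truth["const"] + truth["log_dbh"] * np.log(design["dbh0"].to_numpy())
    for c in ("n_i", "n_h", "n_ii", "n_ih", "n_hi", "n_hh"):
        eta = eta + truth[c] * design[c].to_numpy()
    return eta


def _survival_eta(design: pd.DataFrame, truth: dict[str, float]) -> np.ndarray:
    dbh = design["dbh0"].to_numpy()
    eta = truth["const"] + truth["inv_dbh"] / dbh + truth["dbh"] * dbh + truth["dbh_sq"] * dbh**2
    for c in ("n_i", "n_h", "n_ii", "n_ih", "n_hi", "n_hh"):
        eta = eta + truth[c] * design[c].to_numpy()
    return eta


def growth_recovery_study(
    seed: int, n_reps: int = 200, n_focal: int = 2000, noise_sd: float = 0.5
) -> dict:
    """CI coverage and bias of HOI-inclusive growth-model coefficients.

    One fixed design; per replicate, lognormal growth noise is redrawn and
    the full HOI-inclusive model refitted. Reports per-coefficient 95% CI
    coverage (percent) and mean bias as a percent of the true magnitude.
    """
    root = np.random.SeedSequence(seed)
    design_seed, noise_seed = root.spawn(2)
    design = single_species_design(design_seed, n_focal=n_focal)
    eta = _growth_response(design, GROWTH_TRUTH)
    rng = np.random.default_rng(noise_seed)
    covered = {c: 0 for c in GROWTH_COEFS}
    estimates = {c: [] for c in GROWTH_COEFS}
    data = design.copy()
    for _ in range(n_reps):
        data["growth"] = np.exp(eta + rng.normal(0, noise_sd, len(design)))
        fit = fit_growth(data, "hoi")
        for c in GROWTH_COEFS:
            lo, hi = fit.conf_int[c]
            if lo <= GROWTH_TRUTH[c] <= hi:
                covered[c] += 1
            estimates[c].append(fit.params[c])
    coverage = {c: 100.0 * covered[c] / n_reps for c in GROWTH_COEFS}
    bias_pct = {
        c: 100.0 * abs(float(np.mean(estimates[c])) - GROWTH_TRUTH[c]) / abs(GROWTH_TRUTH[c])
        for c in GROWTH_COEFS
    }
    return {
        "coverage_pct": coverage,
        "bias_pct": bias_pct,
        "n_reps": n_reps,
        "n_obs": len(design),
    }


def survival_recovery_study(seed: int, n_reps: int = 200, n_focal: int = 2000) -> dict:
    """CI coverage of HOI-inclusive survival-model coefficients.

    Fixed design; Bernoulli survival redrawn per replicate from the logistic
    predictor at the true coefficients; Wald 95% intervals from the
    maximum-likelihood logistic fit.
    """
    root = np.random.SeedSequence(seed)
    design_seed, noise_seed = root.spawn(2)
    design = single_species_design(design_seed, n_focal=n_focal)
    p = 1.0 / (1.0 + np.exp(-_survival_eta(design, SURVIVAL_TRUTH)))
    rng = np.random.default_rng(noise_seed)
    covered = {c: 0 for c in SURVIVAL_COEFS}
    used = 0
    data = design.copy()
    for _ in range(n_reps):
        data["survived"] = (rng.random(len(design)) < p).astype(int)
        fit = fit_survival(data, "hoi")
        if fit.ridge_fallback:
            continue  # no Wald intervals from the penalized fallback
        used += 1
        for c in SURVIVAL_COEFS:
            lo, hi = fit.conf_int[c]
            if lo <= SURVIVAL_TRUTH[c] <= hi:
                covered[c] += 1
    coverage = {c: 100.0 * covered[c] / max(used, 1) for c in SURVIVAL_COEFS}
    return {
        "coverage_pct": coverage,
        "n_reps": used,
        "n_obs": len(design),
        "mean_survival": float(p.mean()),
    }


def aic_support_study(seed: int, n_reps: int = 200, n_focal: int = 2000,
                      noise_sd: float = 0.5) -> dict:
    """False and true support rates of the delta-AIC >= 2 rule for HOIs.

    Under a truth with zero higher-order coefficients, the HOI-inclusive
    model should rarely win (the rule's false-support rate); under strong
    higher-order coefficients it should nearly always win.
    """
    root = np.random.SeedSequence(seed)
    design_seed, null_seed, strong_seed = root.spawn(3)
    design = single_species_design(design_seed, n_focal=n_focal)
    null_truth = dict(GROWTH_TRUTH, n_ii=0.0, n_ih=0.0, n_hi=0.0, n_hh=0.0)

    def support_rate(truth: dict, noise_rng: np.random.Generator) -> float:
        eta = _growth_response(design, truth)
        wins = 0
        data = design.copy()
        for _ in range(n_reps):
            data["growth"] = np.exp(eta + noise_rng.normal(0, noise_sd, len(design)))
            fits = fit_all_classes(data, "growth")
            from .models import classify_support

            best = classify_support(
                fits["null"].aic, fits["pair_only"].aic, fits["hoi"].aic
            ).best
            wins += best == "hoi"
        return 100.0 * wins / n_reps

    return {
        "false_support_pct": support_rate(null_truth, np.random.default_rng(null_seed)),
        "true_support_pct": support_rate(GROWTH_TRUTH, np.random.default_rng(strong_seed)),
        "n_reps": n_reps,
        "n_obs": len(design),
    }


def gradient_contrast_study(seed: int, n_reps: int = 50, n_plots: int = 20) -> dict:
    """Recovery of the latitudinal contrast in coefficient magnitudes.

    Replicate 20-plot networks are drawn with intraspecific pairwise
    magnitudes decaying at -0.05/degree and interspecific magnitudes flat
    (the generator defaults). A replicate succeeds when the exponential
    latitude fit on the competitive subset finds a significantly negative
    intraspecific slope and a non-significant interspecific slope.
    """
    rng_seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    successes = 0
    intra_slopes = []
    for s in rng_seeds:
        cfg = SimConfig(n_plots=n_plots, seed=int(s % (2**31)))
        truth = simulate_truth_network(cfg)
        intra = exponential_latitude_fit(
            truth["alpha_ii"], truth["latitude"], "competitive", "alpha_ii"
        )
        inter = exponential_latitude_fit(
            truth["alpha_ih"], truth["latitude"], "competitive", "alpha_ih"
        )
        intra_slopes.append(intra.slope)
        if (
            intra.ok and inter.ok
            and intra.slope < 0 and intra.p_value < 0.05
            and inter.p_value >= 0.05
        ):
            successes += 1
    return {
        "success_pct": 100.0 * successes / n_reps,
        "mean_intra_slope": float(np.mean(intra_slopes)),
        "n_reps": n_reps,
    }


def synthetic_rc_records(
    rng: np.random.Generator,
    n_plots: int = 20,
    species_per_plot: int = 25,
    abundance_slope: float = -0.8,
    latitude_slope: float = -0.03,
    interaction: float = 0.0,
    intercept: float = 3.5,
    noise_sd: float = 0.5,
) -> pd.DataFrame:
    """RC records drawn from a known abundance x latitude linear model."""
    lats = np.repeat(np.linspace(2, 52, n_plots), species_per_plot)
    n = len(lats)
    log_abund = rng.normal(3.0, 1.0, n)
    log_rc = (
        intercept
        + abundance_slope * log_abund
        + latitude_slope * lats
        + interaction * log_abund * lats
        + rng.normal(0, noise_sd, n)
    )
    return pd.DataFrame(
        {
            "sp": [f"s{i}" for i in range(n)],
            "plot_id": np.repeat([f"P{i}" for i in range(n_plots)], species_per_plot),
            "rc_pair": np.exp(log_rc),  # same generative form for both responses
            "rc_hoi": np.exp(log_rc),
            "abundance": np.exp(log_abund),
            "latitude_abs": lats,
            "n_trees": 100,
        }
    )


def rc_recovery_study(seed: int, n_reps: int = 200, abundance_slope: float = -0.8) -> dict:
    """Coverage of the RC-model abundance coefficient, plus a parallelism check.

    Replicate synthetic RC tables are generated with a known abundance slope
    and zero abundance x latitude interaction; coverage counts how often the
    fitted 95% CI contains the true slope. The parallelism check fits a
    noiseless table (interaction exactly zero) and measures the maximum
    slope difference between the three zone prediction curves.
    """
    from .diversity import rc_abundance_latitude_model, zone_predictions

    rng = np.random.default_rng(seed)
    covered = 0
    estimates = []
    for _ in range(n_reps):
        records = synthetic_rc_records(rng, abundance_slope=abundance_slope)
        res = rc_abundance_latitude_model(records, "rc_hoi")
        lo, hi = res.conf_int().loc["log_abundance"]
        covered += lo <= abundance_slope <= hi
        estimates.append(float(res.params["log_abundance"]))

    noiseless = synthetic_rc_records(rng, abundance_slope=abundance_slope, noise_sd=0.0)
    res0 = rc_abundance_latitude_model(noiseless, "rc_hoi")
    grid = np.geomspace(1, 1000, 7)
    zones = zone_predictions(res0, grid)
    slopes = [
        np.polyfit(np.log(grid), z["predicted"].to_numpy(), 1)[0]
        for _, z in zones.groupby("zone")
    ]
    return {
        "coverage_pct": 100.0 * covered / n_reps,
        "mean_estimate": float(np.mean(estimates)),
        "zone_slope_spread": float(np.ptp(slopes)),
        "n_reps": n_reps,
    }
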