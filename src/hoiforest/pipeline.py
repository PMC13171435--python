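"""End-to-end analysis runs: simulate/load -> indices -> fits -> gradients -> RC.

A single YAML config drives a reproducible run. Every stage is a pure
function of its declared inputs and the seed; the run manifest records the
config hash, seeds and a checksum per output so identical configs can be
verified to reproduce identical results.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .census import (
    LinkReport,
    PlotMeta,
    apply_species_filters,
    link_censuses,
    main_stems,
    read_census_table,
    read_plot_metadata,
)
from .diversity import compute_rc, rc_model_summary, rc_records_frame, zone_predictions
from .gradients import (
    alpha_beta_correlation,
    exponential_latitude_fit,
    plot_level_summary,
    quadrat_richness,
    richness_gradient,
)
from .models import (
    MODEL_CLASSES,
    classify_support,
    fit_all_classes,
    predicted_observed_correlation,
    support_summary,
)
from .neighborhood import CrowdingConfig, compute_crowding_table
from .simulate import SimConfig, simulate_network

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output": "hoiforest_run",
    "io": {"fixture_dir": None, "schema": {}},
    "neighborhood": {
        "radius": 10.0,
        "size_exponent": 1.0,
        "distance_exponent": 1.0,
        "min_distance": 0.1,
        "exclude_focal_from_neighbor_crowding": True,
        "standardize": False,
    },
    "models": {
        "growth_floor": 0.01,
        "nonpositive_policy": "floor",
        "responses": ["growth", "survival"],
    },
    "gradients": {"quadrat": 100.0},
    "rc": {"min_species": 4},
    "simulate": None,
}


class ConfigError(ValueError):
    """The run configuration is invalid."""


def validate_config(config) -> dict:
    """Normalize a config (path, YAML string path or dict) and fill defaults.

    Unknown keys produce a warning naming the nearest valid key;
    incompatibilities (e.g. a neighbourhood radius larger than half the
    simulated plot extent) raise :class:`ConfigError`.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    norm = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in config.items():
        if key not in norm:
            near = difflib.get_close_matches(key, list(norm), n=1)
            hint = f"; did you mean {near[0]!r}?" if near else ""
            logger.warning("unknown config key %r%s", key, hint)
            continue
        if isinstance(norm[key], dict) and isinstance(value, dict):
            for k2, v2 in value.items():
                if key != "simulate" and k2 not in norm[key]:
                    near = difflib.get_close_matches(k2, list(norm[key]), n=1)
                    hint = f"; did you mean {near[0]!r}?" if near else ""
                    logger.warning("unknown config key %r in %r%s", k2, key, hint)
                    continue
                norm[key][k2] = v2
        else:
            norm[key] = value

    if norm["simulate"] is None and not norm["io"]["fixture_dir"]:
        raise ConfigError("config needs either a 'simulate' block or io.fixture_dir")
    if norm["simulate"] is not None:
        sim = dict(norm["simulate"])
        sim.setdefault("seed", norm["seed"])
        known = {f.name for f in dataclasses.fields(SimConfig)}
        for k in list(sim):
            if k not in known:
                near = difflib.get_close_matches(k, sorted(known), n=1)
                hint = f"; did you mean {near[0]!r}?" if near else ""
                logger.warning("unknown config key %r in 'simulate'%s", k, hint)
                del sim[k]
        cfg = SimConfig.from_dict(sim)
        if norm["neighborhood"]["radius"] > min(cfg.plot_extent) / 2:
            raise ConfigError(
                f"neighbourhood radius {norm['neighborhood']['radius']} m exceeds half "
                f"the plot extent {min(cfg.plot_extent)} m"
            )
        norm["simulate"] = cfg.to_dict()
    return norm


def crowding_config(config: dict) -> CrowdingConfig:
    return CrowdingConfig(**config["neighborhood"])


def analyze_plot(
    census1: pd.DataFrame,
    census2: pd.DataFrame,
    meta: PlotMeta,
    config: dict,
) -> dict:
    """Run the per-plot stages: link, crowding, per-species nested fits, RC.

    Returns a dict with the linked dynamics, crowding profiles, a tidy
    coefficient table (one row per species x response), support records and
    RC records. Only interior stems of filter-eligible species are fitted.
    """
    ncfg = crowding_config(config)
    mcfg = config["models"]
    report = LinkReport()
    dyn = link_censuses(
        census1, census2, meta,
        growth_floor=mcfg["growth_floor"],
        nonpositive_policy=mcfg["nonpositive_policy"],
        report=report,
    )
    eligible = {r: apply_species_filters(dyn, r) for r in mcfg["responses"]}
    all_species = sorted(set().union(*eligible.values())) if eligible else []
    c1_main = main_stems(census1)
    profiles = compute_crowding_table(
        c1_main, meta.x_extent, meta.y_extent, ncfg, species=all_species or None
    )
    data = dyn.merge(
        profiles.drop(columns=["sp"]), on=["treeID", "stemID"], how="inner"
    )

    coef_rows, supports, rc_records, corr_rows = [], [], [], []
    for response in mcfg["responses"]:
        for sp in eligible[response]:
            sub = data[(data["sp"] == sp) & data["interior"]]
            if response == "growth":
                sub = sub[(sub["survived"] == 1) & (sub["growth"] > 0)]
            if len(sub) < 10 or (
                response == "survival"
                and (sub["survived"].sum() < 2 or (1 - sub["survived"]).sum() < 2)
            ):
                continue
            fits = fit_all_classes(sub, response, species=sp, plot_id=meta.plot_id)
            support = classify_support(
                fits["null"].aic, fits["pair_only"].aic, fits["hoi"].aic,
                species=sp, plot_id=meta.plot_id, response=response,
            )
            supports.append(support)
            row = {
                "plot_id": meta.plot_id,
                "latitude": meta.latitude,
                "sp": sp,
                "response": response,
                "n_obs": fits["hoi"].n_obs,
                "support": support.best,
                "degenerate": fits["hoi"].degenerate,
                "aic_null": fits["null"].aic,
                "aic_pair": fits["pair_only"].aic,
                "aic_hoi": fits["hoi"].aic,
                "alpha_ii_modified": fits["pair_only"].coefficient("n_i"),
                "alpha_ih_modified": fits["pair_only"].coefficient("n_h"),
                "alpha_ii_true": fits["hoi"].coefficient("n_i"),
                "alpha_ih_true": fits["hoi"].coefficient("n_h"),
                "beta_iii": fits["hoi"].coefficient("n_ii"),
                "beta_iih": fits["hoi"].coefficient("n_ih"),
                "beta_ihi": fits["hoi"].coefficient("n_hi"),
                "beta_ihh": fits["hoi"].coefficient("n_hh"),
            }
            coef_rows.append(row)
            if response == "growth":
                corr = predicted_observed_correlation(fits, sub)
                corr_rows.append(
                    {"plot_id": meta.plot_id, "sp": sp, **{f"r_{k}": v for k, v in corr.items()}}
                )
                if not fits["hoi"].degenerate:
                    prof_sp = data[(data["sp"] == sp) & data["interior"]]
                    n_tot = int((dyn["sp"] == sp).sum())
                    rc_records.append(
                        compute_rc(
                            fits["hoi"], prof_sp,
                            abundance=n_tot / meta.area_ha,
                            latitude=meta.latitude,
                        )
                    )
    richness = quadrat_richness(
        c1_main, meta.x_extent, meta.y_extent, config["gradients"]["quadrat"]
    )
    return {
        "dynamics": dyn,
        "profiles": profiles,
        "coefficients": pd.DataFrame(coef_rows),
        "supports": supports,
        "correlations": pd.DataFrame(corr_rows),
        "rc_records": rc_records,
        "richness": richness,
        "link_report": report,
    }


def _load_fixture(config: dict):
    fdir = Path(config["io"]["fixture_dir"])
    metas = read_plot_metadata(fdir / "plots.tsv")
    schema = config["io"].get("schema") or None
    plots = {}
    for meta in metas:
        c1 = read_census_table(
            fdir / f"{meta.plot_id}_census1.tsv", schema,
            x_extent=meta.x_extent, y_extent=meta.y_extent,
        )
        c2 = read_census_table(
            fdir / f"{meta.plot_id}_census2.tsv", schema,
            x_extent=meta.x_extent, y_extent=meta.y_extent,
        )
        plots[meta.plot_id] = (c1, c2, meta)
    return plots


def gradient_table(coefficients: pd.DataFrame) -> pd.DataFrame:
    """Exponential latitude fits for every coefficient type x sign subset.

    Uses growth-model coefficients, excluding species flagged degenerate.
    """
    coef_cols = [
        "alpha_ii_true", "alpha_ii_modified", "alpha_ih_true", "alpha_ih_modified",
        "beta_iii", "beta_iih", "beta_ihi", "beta_ihh",
    ]
    sub = coefficients[(coefficients["response"] == "growth") & ~coefficients["degenerate"]]
    rows = []
    for col in coef_cols:
        for subset in ("competitive", "facilitative"):
            fit = exponential_latitude_fit(
                sub[col].to_numpy(), sub["latitude"].to_numpy(), subset, col
            )
            rows.append(dataclasses.asdict(fit))
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config, output_dir=None) -> dict:
    """Run the full pipeline and write all summary tables plus a manifest.

    Returns the report dict (also written as ``report.json``). Outputs:
    coefficient table, support summary, predictive-correlation table,
    gradient table, plot-level coefficient summary, RC table and Table-1
    style RC model summary, richness gradient, and a run manifest with
    config hash and per-file checksums.
    """
    config = validate_config(config)
    outdir = Path(output_dir or config["output"])
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings = {}

    if config["io"]["fixture_dir"]:
        plots = _load_fixture(config)
    else:
        sim_cfg = SimConfig.from_dict(config["simulate"])
        network = simulate_network(sim_cfg, crowding_cfg=crowding_config(config))
        network_truth = network.truth
        network_truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        plots = network.plots
    timings["inputs"] = time.time() - t0

    all_coefs, all_supports, all_corr, all_rc = [], [], [], []
    richness_rows = []
    t1 = time.time()
    for pid, (c1, c2, meta) in plots.items():
        result = analyze_plot(c1, c2, meta, config)
        all_coefs.append(result["coefficients"])
        all_supports.extend(result["supports"])
        all_corr.append(result["correlations"])
        all_rc.extend(result["rc_records"])
        richness_rows.append(
            {"plot_id": pid, "latitude": meta.latitude, "richness": result["richness"]}
        )
    timings["fits"] = time.time() - t1

    coefficients = pd.concat(all_coefs, ignore_index=True)
    correlations = pd.concat(all_corr, ignore_index=True)
    richness = pd.DataFrame(richness_rows)

    report: dict = {"version": __version__, "seed": config["seed"], "n_plots": len(plots)}
    for response in config["models"]["responses"]:
        recs = [s for s in all_supports if s.response == response]
        if recs:
            report[f"support_{response}"] = support_summary(recs)

    grad = gradient_table(coefficients)
    plevel = plot_level_summary(
        coefficients[coefficients["response"] == "growth"],
        ["alpha_ii_true", "alpha_ih_true", "beta_iii", "beta_iih", "beta_ihi", "beta_ihh"],
    )
    ab_corr = alpha_beta_correlation(
        coefficients[coefficients["response"] == "growth"]
        .rename(columns={"alpha_ii_true": "alpha_ii", "alpha_ih_true": "alpha_ih"})
    )
    rich_fit = richness_gradient(richness["richness"], richness["latitude"])
    report["richness_gradient"] = dataclasses.asdict(rich_fit)

    rc_df = rc_records_frame(all_rc)
    rc_summary = pd.DataFrame()
    zone_df = pd.DataFrame()
    if len(rc_df) >= config["rc"]["min_species"]:
        rc_summary = rc_model_summary(rc_df)
        from .diversity import rc_abundance_latitude_model

        grid = np.geomspace(rc_df["abundance"].min(), rc_df["abundance"].max(), 25)
        zone_df = zone_predictions(rc_abundance_latitude_model(rc_df, "rc_hoi"), grid)
        report["rc_model"] = {
            r: {
                row["term"]: row["estimate"]
                for _, row in rc_summary[rc_summary["response"] == r].iterrows()
            }
            for r in ("rc_pair", "rc_hoi")
        }

    tables = {
        "coefficients.tsv": coefficients,
        "support_correlations.tsv": correlations,
        "gradients.tsv": grad,
        "plot_level_summary.tsv": plevel,
        "alpha_beta_correlation.tsv": ab_corr,
        "richness.tsv": richness,
        "rc_records.tsv": rc_df,
        "rc_model.tsv": rc_summary,
        "zone_predictions.tsv": zone_df,
    }
    for name, df in tables.items():
        df.to_csv(outdir / name, sep="\t", index=False, float_format="%.10g")

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)

    cfg_json = json.dumps(
        {k: v for k, v in config.items() if k != "output"}, sort_keys=True, default=float
    )
    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config["seed"],
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {
            name: _sha256(outdir / name) for name in [*tables, "report.json"]
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report
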