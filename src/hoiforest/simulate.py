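"""Synthetic multi-plot mapped forests with known interaction coefficients.

The generator produces two-census stem tables from the same generative model
the inference fits: census-1 stems get positions (Poisson or Thomas-cluster
point patterns), species (log-series or uniform abundances) and truncated
lognormal DBHs; species-level pairwise (alpha) and higher-order (beta)
coefficients are drawn with magnitudes that decay exponentially with absolute
latitude; growth is lognormal around ``G_i * DBH**gamma * exp(Pair + HOI)``
and interval survival is Bernoulli from the logistic size-and-neighbourhood
predictor. Census 2 contains the survivors with their grown DBH plus the dead
stems. Everything is deterministic given the seed, and the true coefficients
are recorded so that estimation bias, coverage and gradient recovery can be
measured exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .census import PlotMeta, write_census_table, write_plot_metadata
from .neighborhood import CrowdingConfig, compute_crowding_table

COEFFICIENT_TYPES = ["alpha_ii", "alpha_ih", "beta_iii", "beta_iih", "beta_ihi", "beta_ihh"]

_INDEX_FOR_COEF = {
    "alpha_ii": "n_i",
    "alpha_ih": "n_h",
    "beta_iii": "n_ii",
    "beta_iih": "n_ih",
    "beta_ihi": "n_hi",
    "beta_ihh": "n_hh",
}


@dataclass(frozen=True)
class CoefficientPrior:
    """Generative distribution for one interaction-coefficient type.

    Magnitudes are ``scale * exp(decay * |lat|)`` times a lognormal spread
    with log-sd `sd_log`; `decay` < 0 makes interactions weaken polewards.
    The sign is facilitative (+) with probability `facilitative_fraction`,
    else competitive (−).
    """

    scale: float
    decay: float = 0.0
    facilitative_fraction: float = 0.5
    sd_log: float = 0.5

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.sd_log < 0:
            raise ValueError("scale must be positive, sd_log non-negative")
        if not 0 <= self.facilitative_fraction <= 1:
            raise ValueError("facilitative_fraction must lie in [0, 1]")

    def draw(self, rng: np.random.Generator, latitude: float, size: int) -> np.ndarray:
        mag = self.scale * np.exp(self.decay * abs(latitude))
        mag = mag * rng.lognormal(0.0, self.sd_log, size)
        sign = np.where(rng.random(size) < self.facilitative_fraction, 1.0, -1.0)
        return sign * mag


def default_priors() -> dict[str, CoefficientPrior]:
    """Priors emulating the observed latitudinal pattern: intraspecific
    pairwise and most higher-order magnitudes decay with latitude while the
    interspecific pairwise and the het-het higher-order channel stay flat;
    competitive and facilitative signs are equally frequent."""
    return {
        "alpha_ii": CoefficientPrior(scale=8e-3, decay=-0.05),
        "alpha_ih": CoefficientPrior(scale=4e-3, decay=0.0),
        "beta_iii": CoefficientPrior(scale=1e-4, decay=-0.05),
        "beta_iih": CoefficientPrior(scale=1e-4, decay=-0.05),
        "beta_ihi": CoefficientPrior(scale=1e-4, decay=-0.05),
        "beta_ihh": CoefficientPrior(scale=1e-4, decay=0.0),
    }


@dataclass
class SimConfig:
    """Study design of a synthetic forest network.

    Defaults emulate a desk-scale version of a multi-plot census network:
    20 one-hectare plots spaced along 2–52 degrees absolute latitude,
    ~1,500 stems/ha above the 1 cm DBH census threshold, log-series species
    abundances with equatorial richness 60 decaying at 0.03/degree, truncated
    lognormal DBHs, a 5-year census interval and multiplicative lognormal
    growth noise (sd 0.5 on the log scale).
    """

    n_plots: int = 20
    latitude_range: tuple[float, float] = (2.0, 52.0)
    plot_extent: tuple[float, float] = (100.0, 100.0)
    stem_density: float = 0.15  # stems per m^2
    richness_at_equator: int = 60
    richness_decay: float = 0.03  # per degree of absolute latitude
    abundance_model: str = "logseries"  # or "uniform"
    logseries_p: float = 0.95
    spatial_pattern: str = "poisson"  # or "thomas"
    thomas_cluster_radius: float = 5.0
    thomas_mean_offspring: float = 10.0
    dbh_mu: float = float(np.log(3.0))  # lognormal log-mean, cm
    dbh_sigma: float = 0.8
    census_interval: float = 5.0  # years
    growth_noise_sd: float = 0.5  # log scale
    log_G_mean: float = float(np.log(0.2))  # potential growth, cm/yr at DBH 1
    log_G_sd: float = 0.3
    gamma_mean: float = 0.4
    gamma_sd: float = 0.1
    survival_lambda_mean: float = 2.0
    survival_lambda_sd: float = 0.3
    survival_gamma1: float = -0.8
    survival_gamma2: float = 0.02
    survival_gamma3: float = -2e-4
    coefficient_priors: dict[str, CoefficientPrior] = field(default_factory=default_priors)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stem_density <= 0 or min(self.plot_extent) <= 0:
            raise ValueError("density and extents must be positive")
        if self.abundance_model not in ("logseries", "uniform"):
            raise ValueError("abundance_model must be 'logseries' or 'uniform'")
        if self.spatial_pattern not in ("poisson", "thomas"):
            raise ValueError("spatial_pattern must be 'poisson' or 'thomas'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coefficient_priors"] = {
            k: dataclasses.asdict(v) for k, v in self.coefficient_priors.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "coefficient_priors" in d:
            d["coefficient_priors"] = {
                k: CoefficientPrior(**v) if not isinstance(v, CoefficientPrior) else v
                for k, v in d["coefficient_priors"].items()
            }
        if "latitude_range" in d:
            d["latitude_range"] = tuple(d["latitude_range"])
        if "plot_extent" in d:
            d["plot_extent"] = tuple(d["plot_extent"])
        return cls(**d)


def plot_latitudes(cfg: SimConfig) -> np.ndarray:
    """Evenly spaced plot latitudes across the configured range."""
    lo, hi = cfg.latitude_range
    return np.linspace(lo, hi, cfg.n_plots)


def plot_richness(cfg: SimConfig, latitude: float) -> int:
    """Expected species richness ``S0 * exp(-k |lat|)``, at least 2."""
    return max(2, int(round(cfg.richness_at_equator * np.exp(-cfg.richness_decay * abs(latitude)))))


def _species_probabilities(cfg: SimConfig, rng: np.random.Generator, s: int) -> np.ndarray:
    if cfg.abundance_model == "uniform":
        return np.full(s, 1.0 / s)
    from scipy import stats

    counts = stats.logser.rvs(cfg.logseries_p, size=s, random_state=rng).astype(float)
    return counts / counts.sum()


def _positions(cfg: SimConfig, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ex, ey = cfg.plot_extent
    if cfg.spatial_pattern == "poisson":
        return rng.uniform(0, ex, n), rng.uniform(0, ey, n)
    # Thomas process: Gaussian clusters around uniform parents, wrapped by
    # rejection into the plot; realized n matches the requested n.
    n_parents = max(1, int(round(n / cfg.thomas_mean_offspring)))
    px = rng.uniform(0, ex, n_parents)
    py = rng.uniform(0, ey, n_parents)
    xs: list[float] = []
    ys: list[float] = []
    while len(xs) < n:
        k = rng.integers(0, n_parents)
        x = rng.normal(px[k], cfg.thomas_cluster_radius)
        y = rng.normal(py[k], cfg.thomas_cluster_radius)
        if 0 <= x <= ex and 0 <= y <= ey:
            xs.append(x)
            ys.append(y)
    return np.array(xs), np.array(ys)


def _truncated_lognormal_dbh(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(cfg.dbh_mu, cfg.dbh_sigma, 2 * (n - filled) + 16)
        draw = draw[draw >= 1.0]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def draw_species_truth(
    cfg: SimConfig, rng: np.random.Generator, latitude: float, species: list[str]
) -> pd.DataFrame:
    """True demographic and interaction parameters for each species."""
    s = len(species)
    truth = pd.DataFrame({"sp": species})
    truth["log_G"] = rng.normal(cfg.log_G_mean, cfg.log_G_sd, s)
    truth["gamma"] = rng.normal(cfg.gamma_mean, cfg.gamma_sd, s)
    truth["lambda"] = rng.normal(cfg.survival_lambda_mean, cfg.survival_lambda_sd, s)
    truth["gamma1"] = cfg.survival_gamma1
    truth["gamma2"] = cfg.survival_gamma2
    truth["gamma3"] = cfg.survival_gamma3
    for coef in COEFFICIENT_TYPES:
        truth[coef] = cfg.coefficient_priors[coef].draw(rng, latitude, s)
    truth["latitude"] = latitude
    return truth


def simulate_plot(
    cfg: SimConfig,
    latitude: float,
    seed,
    *,
    plot_id: str = "plot",
    crowding_cfg: CrowdingConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, PlotMeta]:
    """Simulate one plot's two censuses from the generative model.

    Returns ``(census1, census2, truth, meta)``. Crowding indices are
    computed with `crowding_cfg` (defaults match inference defaults), growth
    is drawn lognormally around the deterministic growth model and survival
    is Bernoulli from the logistic predictor. Deterministic given `seed`.
    """
    rng = np.random.default_rng(seed)
    crowding_cfg = crowding_cfg or CrowdingConfig()
    ex, ey = cfg.plot_extent
    n = int(rng.poisson(cfg.stem_density * ex * ey))
    if n == 0:
        raise ValueError("configuration produced an empty plot")

    s = plot_richness(cfg, latitude)
    species = [f"sp{j:03d}" for j in range(s)]
    probs = _species_probabilities(cfg, rng, s)
    sp = rng.choice(species, size=n, p=probs)
    gx, gy = _positions(cfg, rng, n)
    dbh = _truncated_lognormal_dbh(cfg, rng, n)

    census1 = pd.DataFrame(
        {
            "treeID": [f"t{i:06d}" for i in range(n)],
            "stemID": ["1"] * n,
            "sp": sp,
            "gx": gx,
            "gy": gy,
            "dbh": dbh,
            "status": "alive",
            "date": 2000.0,
        }
    )
    truth = draw_species_truth(cfg, rng, latitude, species)
    truth.insert(0, "plot_id", plot_id)

    profiles = compute_crowding_table(census1, ex, ey, crowding_cfg)
    tmap = truth.set_index("sp")
    pair = np.zeros(n)
    hoi = np.zeros(n)
    prof = profiles.sort_index()
    for a_name in ("alpha_ii", "alpha_ih"):
        pair += tmap[a_name].loc[prof["sp"]].to_numpy() * prof[_INDEX_FOR_COEF[a_name]].to_numpy()
    for b_name in ("beta_iii", "beta_iih", "beta_ihi", "beta_ihh"):
        hoi += tmap[b_name].loc[prof["sp"]].to_numpy() * prof[_INDEX_FOR_COEF[b_name]].to_numpy()

    log_G = tmap["log_G"].loc[sp].to_numpy()
    gamma = tmap["gamma"].loc[sp].to_numpy()
    noise = rng.normal(0.0, cfg.growth_noise_sd, n)
    growth = np.exp(log_G + gamma * np.log(dbh) + pair + hoi + noise)

    lam = tmap["lambda"].loc[sp].to_numpy()
    eta = (
        lam
        + cfg.survival_gamma1 / dbh
        + cfg.survival_gamma2 * dbh
        + cfg.survival_gamma3 * dbh**2
        + pair
        + hoi
    )
    p_surv = 1.0 / (1.0 + np.exp(-eta))
    survived = rng.random(n) < p_surv

    dt = cfg.census_interval
    census2 = census1.copy()
    census2["date"] = 2000.0 + dt
    census2.loc[survived, "dbh"] = dbh[survived] + growth[survived] * dt
    census2["status"] = np.where(survived, "alive", "dead")

    meta = PlotMeta(
        plot_id=plot_id,
        latitude=float(latitude),
        x_extent=ex,
        y_extent=ey,
        census_dates=(2000.0, 2000.0 + dt),
    )
    return census1, census2, truth, meta


@dataclass
class SimulatedNetwork:
    """A set of simulated plots with shared config and recorded truth."""

    config: SimConfig
    plots: dict[str, tuple[pd.DataFrame, pd.DataFrame, PlotMeta]]
    truth: pd.DataFrame

    @property
    def metas(self) -> list[PlotMeta]:
        return [m for (_, _, m) in self.plots.values()]


def simulate_network(
    cfg: SimConfig, *, crowding_cfg: CrowdingConfig | None = None
) -> SimulatedNetwork:
    """Simulate all plots of a latitudinal network (deterministic per seed)."""
    if cfg.n_plots < 2:
        raise ValueError("a network needs at least 2 plots")
    lats = plot_latitudes(cfg)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_plots)
    plots = {}
    truths = []
    for i, (lat, child) in enumerate(zip(lats, children)):
        pid = f"P{i:02d}"
        c1, c2, truth, meta = simulate_plot(
            cfg, lat, child, plot_id=pid, crowding_cfg=crowding_cfg
        )
        plots[pid] = (c1, c2, meta)
        truths.append(truth)
    return SimulatedNetwork(cfg, plots, pd.concat(truths, ignore_index=True))


def simulate_truth_network(cfg: SimConfig) -> pd.DataFrame:
    """Species-level truth coefficients for a network, without stem data.

    Fast path for replicate studies of the coefficient-gradient recovery:
    plots are placed at the same latitudes and species coefficients drawn
    from the same priors as :func:`simulate_network`, but no point pattern,
    crowding or demography is generated.
    """
    lats = plot_latitudes(cfg)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_plots)
    truths = []
    for i, (lat, child) in enumerate(zip(lats, children)):
        rng = np.random.default_rng(child)
        s = plot_richness(cfg, lat)
        species = [f"sp{j:03d}" for j in range(s)]
        truth = draw_species_truth(cfg, rng, lat, species)
        truth.insert(0, "plot_id", f"P{i:02d}")
        truths.append(truth)
    return pd.concat(truths, ignore_index=True)


def write_fixture(network: SimulatedNetwork, directory) -> dict:
    """Write a network as census/metadata/truth text files plus a manifest.

    The layout round-trips through :mod:`hoiforest.census`, and the manifest
    records the full config and seed so the fixture can be regenerated
    bit-identically with :func:`simulate_network`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for pid, (c1, c2, meta) in network.plots.items():
        for tag, df in (("census1", c1), ("census2", c2)):
            path = directory / f"{pid}_{tag}.tsv"
            write_census_table(df, path)
            files.append(path.name)
    write_plot_metadata(network.metas, directory / "plots.tsv")
    network.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
    files += ["plots.tsv", "truth.tsv"]
    manifest = {
        "seed": network.config.seed,
        "config": network.config.to_dict(),
        "files": files,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
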