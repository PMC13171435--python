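"""Reading, validating and linking two-census mapped stem tables.

A census table has one row per stem per census. The canonical columns are
``treeID, stemID, sp, gx, gy, dbh, status, date``; other dialects are mapped
onto these via a schema dictionary. Two censuses of the same plot are linked
into per-stem demographic records (annualized DBH growth and interval
survival) on which all downstream models operate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column names for a stem census table.
CANONICAL_COLUMNS = ["treeID", "stemID", "sp", "gx", "gy", "dbh", "status", "date"]

#: Minimum DBH (cm) for a live stem to enter the census.
CENSUS_MIN_DBH = 1.0

VALID_STATUS = {"alive", "dead", "recruit"}


class SchemaError(ValueError):
    """A required column is missing from a census table."""


class CensusValidationError(ValueError):
    """A census row violates a structural invariant (e.g. out-of-bounds coordinate)."""


class CensusConsistencyError(ValueError):
    """The two censuses of a plot disagree (e.g. an unexplained new stem)."""


@dataclass(frozen=True)
class PlotMeta:
    """Metadata for one mapped forest plot.

    Parameters
    ----------
    plot_id : str
        Unique plot identifier.
    latitude : float
        Signed latitude in decimal degrees (negative = southern hemisphere).
    x_extent, y_extent : float
        Plot dimensions in metres; stem coordinates live in
        ``[0, x_extent] x [0, y_extent]``.
    census_dates : tuple of float
        Decimal years of the two censuses, in order.
    longitude : float, optional
        Signed longitude in decimal degrees.
    """

    plot_id: str
    latitude: float
    x_extent: float
    y_extent: float
    census_dates: tuple[float, float]
    longitude: float = 0.0

    def __post_init__(self) -> None:
        if self.x_extent <= 0 or self.y_extent <= 0:
            raise ValueError("plot extents must be positive")
        if abs(self.latitude) > 90:
            raise ValueError("latitude must lie in [-90, 90]")
        if self.census_interval <= 0:
            raise ValueError("census interval must be positive")

    @property
    def census_interval(self) -> float:
        """Inter-census interval in years."""
        return self.census_dates[1] - self.census_dates[0]

    @property
    def area_ha(self) -> float:
        """Plot area in hectares."""
        return self.x_extent * self.y_extent / 1e4


def read_census_table(
    path,
    schema: dict[str, str] | None = None,
    *,
    x_extent: float | None = None,
    y_extent: float | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read and validate one census into a canonical stem table.

    Parameters
    ----------
    path : str or path-like
        Delimited text file, one row per stem. Comma or tab delimiters are
        auto-detected unless `sep` is given.
    schema : dict, optional
        Mapping from the file's column names to the canonical names in
        :data:`CANONICAL_COLUMNS` (only non-canonical columns need an entry).
    x_extent, y_extent : float, optional
        If given, stem coordinates are checked against ``[0, extent]`` and an
        out-of-bounds row raises :class:`CensusValidationError`.

    Returns
    -------
    pandas.DataFrame
        Canonical columns; live stems with DBH below the 1 cm census minimum
        are dropped with a logged reason.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"census table {path} missing required columns: {missing}")
    df = df[CANONICAL_COLUMNS].copy()
    df["treeID"] = df["treeID"].astype(str)
    df["stemID"] = df["stemID"].astype(str)
    df["sp"] = df["sp"].astype(str)
    df["status"] = df["status"].astype(str).str.lower()

    bad_status = ~df["status"].isin(VALID_STATUS)
    if bad_status.any():
        rows = df.index[bad_status].tolist()
        raise CensusValidationError(f"unknown status in rows {rows[:10]} of {path}")

    for axis, extent in (("gx", x_extent), ("gy", y_extent)):
        if extent is not None:
            out = (df[axis] < 0) | (df[axis] > extent)
            if out.any():
                rows = df.index[out].tolist()
                raise CensusValidationError(
                    f"{axis} outside [0, {extent}] in rows {rows[:10]} of {path}"
                )
        elif (df[axis] < 0).any():
            rows = df.index[df[axis] < 0].tolist()
            raise CensusValidationError(f"negative {axis} in rows {rows[:10]} of {path}")

    undersized = (df["status"] != "dead") & (df["dbh"] < CENSUS_MIN_DBH)
    if undersized.any():
        logger.info(
            "%s: rejected %d rows, reason: dbh below census minimum (%.1f cm)",
            path, int(undersized.sum()), CENSUS_MIN_DBH,
        )
        df = df[~undersized]
    return df.reset_index(drop=True)


def write_census_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a canonical stem table; round-trips through :func:`read_census_table`."""
    df.to_csv(path, sep=sep, index=False, columns=CANONICAL_COLUMNS)


def read_plot_metadata(path, sep: str | None = None) -> list[PlotMeta]:
    """Read a one-row-per-plot metadata table.

    Expected columns: ``plot_id, latitude, x_extent, y_extent, date1, date2``
    and optionally ``longitude``.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    required = ["plot_id", "latitude", "x_extent", "y_extent", "date1", "date2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"plot metadata {path} missing columns: {missing}")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            PlotMeta(
                plot_id=str(row["plot_id"]),
                latitude=float(row["latitude"]),
                x_extent=float(row["x_extent"]),
                y_extent=float(row["y_extent"]),
                census_dates=(float(row["date1"]), float(row["date2"])),
                longitude=float(row.get("longitude", 0.0)),
            )
        )
    return metas


def write_plot_metadata(metas: list[PlotMeta], path, sep: str = "\t") -> None:
    rows = [
        {
            "plot_id": m.plot_id,
            "latitude": m.latitude,
            "longitude": m.longitude,
            "x_extent": m.x_extent,
            "y_extent": m.y_extent,
            "date1": m.census_dates[0],
            "date2": m.census_dates[1],
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def main_stems(census: pd.DataFrame) -> pd.DataFrame:
    """Reduce a census to one main stem per tree (largest DBH; stemID tiebreak)."""
    df = census.sort_values(["dbh", "stemID"], ascending=[False, True], kind="mergesort")
    return df.drop_duplicates("treeID", keep="first").sort_index().reset_index(drop=True)


@dataclass
class LinkReport:
    """Bookkeeping from :func:`link_censuses` for auditability."""

    n_census1: int = 0
    n_dynamics: int = 0
    n_recruits_excluded: int = 0
    n_nonpositive_growth: int = 0
    notes: list[str] = field(default_factory=list)


def link_censuses(
    census1: pd.DataFrame,
    census2: pd.DataFrame,
    meta: PlotMeta,
    *,
    growth_floor: float = 0.01,
    nonpositive_policy: str = "floor",
    report: LinkReport | None = None,
) -> pd.DataFrame:
    """Link two censuses into per-stem demographic records.

    Multi-stem trees are reduced to their main stem (largest census-1 DBH).
    Every census-1 main stem yields exactly one record. Survival is 1 iff the
    stem is present and alive in census 2; annualized growth
    ``(dbh2 - dbh1) / dt`` (cm/yr) is defined for survivors only. Non-positive
    increments are replaced by `growth_floor` (``nonpositive_policy="floor"``,
    required by the log-linear growth model) or set to NaN and excluded
    (``"drop"``); the count is logged either way. Recruits new in census 2 are
    excluded as focal observations.

    Raises
    ------
    CensusConsistencyError
        If a census-2 stem absent from census 1 is not flagged ``recruit``.
    """
    if nonpositive_policy not in ("floor", "drop"):
        raise ValueError("nonpositive_policy must be 'floor' or 'drop'")
    rep = report if report is not None else LinkReport()
    dt = meta.census_interval

    c1 = main_stems(census1)
    key1 = c1["treeID"] + "\x00" + c1["stemID"]
    c2 = census2.copy()
    key2 = c2["treeID"] + "\x00" + c2["stemID"]

    new = ~key2.isin(set(key1)) & ~c2["treeID"].isin(set(c1["treeID"]))
    not_recruit = new & (c2["status"] != "recruit")
    if not_recruit.any():
        rows = c2.index[not_recruit].tolist()
        raise CensusConsistencyError(
            f"{meta.plot_id}: census-2 stems absent from census 1 and not flagged "
            f"recruit, rows {rows[:10]}"
        )
    rep.n_recruits_excluded = int(new.sum())

    c2m = c2.set_index(key2)
    dyn = pd.DataFrame(
        {
            "treeID": c1["treeID"].to_numpy(),
            "stemID": c1["stemID"].to_numpy(),
            "sp": c1["sp"].to_numpy(),
            "gx": c1["gx"].to_numpy(dtype=float),
            "gy": c1["gy"].to_numpy(dtype=float),
            "dbh0": c1["dbh"].to_numpy(dtype=float),
        }
    )
    matched = c2m.reindex(key1.to_numpy())
    alive2 = (matched["status"] == "alive").to_numpy()
    dbh2 = matched["dbh"].to_numpy(dtype=float)

    dyn["survived"] = alive2.astype(int)
    growth = np.full(len(dyn), np.nan)
    growth[alive2] = (dbh2[alive2] - dyn["dbh0"].to_numpy()[alive2]) / dt
    nonpos = alive2 & (growth <= 0)
    rep.n_nonpositive_growth = int(np.nansum(nonpos))
    if rep.n_nonpositive_growth:
        logger.info(
            "%s: %d survivors with non-positive DBH increment (%s policy)",
            meta.plot_id, rep.n_nonpositive_growth, nonpositive_policy,
        )
        if nonpositive_policy == "floor":
            growth[nonpos] = growth_floor
        else:
            growth[nonpos] = np.nan
    dyn["growth"] = growth
    dyn["dt"] = dt
    dyn["plot_id"] = meta.plot_id

    rep.n_census1 = len(c1)
    rep.n_dynamics = len(dyn)
    return dyn


def apply_species_filters(dynamics: pd.DataFrame, response: str) -> list[str]:
    """Return species eligible for model fitting.

    Growth models require more than 100 trees of the species; survival models
    additionally require at least 20 survivors and 20 deaths, so that both
    outcome classes are represented.
    """
    if response not in ("growth", "survival"):
        raise ValueError("response must be 'growth' or 'survival'")
    if len(dynamics) == 0:
        return []
    counts = dynamics.groupby("sp").agg(
        n=("survived", "size"),
        n_surv=("survived", "sum"),
    )
    counts["n_dead"] = counts["n"] - counts["n_surv"]
    keep = counts["n"] > 100
    if response == "survival":
        keep &= (counts["n_surv"] >= 20) & (counts["n_dead"] >= 20)
    return sorted(counts.index[keep])
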