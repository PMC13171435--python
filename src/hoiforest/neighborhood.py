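"""Pairwise and higher-order neighbourhood crowding indices.

Each neighbour within a fixed radius of a focal stem contributes crowding
proportional to its size (DBH) and inversely proportional to its distance.
Summing contributions over conspecific and heterospecific neighbours gives
the pairwise indices ``n_i`` and ``n_h``. The higher-order indices weight
each neighbour's (transmitter's) contribution by that neighbour's own
crowding, split by the initiator's identity *relative to the focal species*:

====== ============ =============================================
index  transmitter  initiator (crowding around the transmitter)
====== ============ =============================================
n_ii   conspecific  focal species i
n_ih   conspecific  all species other than i
n_hi   heterospec.  focal species i
n_hh   heterospec.  all species other than i
====== ============ =============================================

A focal stem therefore sees a non-zero higher-order index only when it has a
transmitter of the right identity that is itself crowded by initiators of the
right identity — the spatial analogue of a three-species interaction chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

CROWDING_COLUMNS = ["n_i", "n_h", "n_ii", "n_ih", "n_hi", "n_hh"]


@dataclass(frozen=True)
class CrowdingConfig:
    """Configuration of the crowding kernel.

    Parameters
    ----------
    radius : float
        Neighbourhood radius in metres; only stems within this distance of
        the focal contribute, and the same radius bounds each transmitter's
        own neighbourhood.
    size_exponent, distance_exponent : float
        A neighbour of diameter ``dbh`` at distance ``d`` contributes
        ``dbh**size_exponent / d**distance_exponent`` crowding units. The
        default (1, 1) is linear in size and inverse in distance; common
        dialects such as ``dbh**2 / d**2`` are one config change.
    min_distance : float
        Distances are clamped below at this value (metres) so co-located
        stems never contribute unbounded crowding.
    exclude_focal_from_neighbor_crowding : bool
        If True (default) the focal stem is removed from each transmitter's
        own neighbourhood, so the focal cannot initiate higher-order effects
        on itself.
    standardize : bool
        If True, divide each index by its within-species standard deviation
        after computation (per plot). Off by default; raw indices keep the
        generative model's coefficients directly recoverable.
    """

    radius: float = 10.0
    size_exponent: float = 1.0
    distance_exponent: float = 1.0
    min_distance: float = 0.1
    exclude_focal_from_neighbor_crowding: bool = True
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")
        for e in (self.size_exponent, self.distance_exponent):
            if not np.isfinite(e):
                raise ValueError("exponents must be finite")


def neighbor_contribution(dbh_j, distance, cfg: CrowdingConfig):
    """Crowding contribution of one neighbour: ``dbh**a / max(d, d_min)**b``.

    Accepts scalars or arrays. Distances at or below zero are clamped to
    ``cfg.min_distance`` (with a logged warning), never producing infinities.
    """
    distance = np.asarray(distance, dtype=float)
    if np.any(distance <= 0):
        logger.warning("non-positive neighbour distance clamped to %.3g m", cfg.min_distance)
    d = np.maximum(distance, cfg.min_distance)
    return np.asarray(dbh_j, dtype=float) ** cfg.size_exponent / d**cfg.distance_exponent


def _neighbor_mask(i: int, x, y, cfg: CrowdingConfig):
    d = np.hypot(x - x[i], y - y[i])
    mask = (d <= cfg.radius) & (np.arange(len(x)) != i)
    return mask, d


def pairwise_indices(focal: int, x, y, dbh, species, cfg: CrowdingConfig):
    """Pairwise crowding indices ``(n_i, n_h)`` of one focal stem.

    Direct (per-definition) implementation: contributions of all conspecific
    and heterospecific stems within ``cfg.radius``, the focal excluded.
    Arrays describe the full census-1 stem set.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    dbh = np.asarray(dbh, float)
    species = np.asarray(species)
    mask, d = _neighbor_mask(focal, x, y, cfg)
    contrib = np.zeros(len(x))
    contrib[mask] = neighbor_contribution(dbh[mask], d[mask], cfg)
    con = species == species[focal]
    return float(contrib[con].sum()), float(contrib[~con].sum())


def higher_order_indices(focal: int, x, y, dbh, species, cfg: CrowdingConfig):
    """Higher-order crowding indices ``(n_ii, n_ih, n_hi, n_hh)`` of one focal stem.

    For each transmitter j within the radius, j's contribution to the focal
    is multiplied by j's own crowding by initiators of species i (the focal
    species) or by all other species, computed within the same radius around
    j, excluding j itself and (by default) the focal stem.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    dbh = np.asarray(dbh, float)
    species = np.asarray(species)
    sp_i = species[focal]
    mask, d = _neighbor_mask(focal, x, y, cfg)
    out = np.zeros(4)
    for j in np.flatnonzero(mask):
        c_fj = float(neighbor_contribution(dbh[j], d[j], cfg))
        jmask, jd = _neighbor_mask(j, x, y, cfg)
        if cfg.exclude_focal_from_neighbor_crowding:
            jmask = jmask.copy()
            jmask[focal] = False
        inner = np.zeros(len(x))
        inner[jmask] = neighbor_contribution(dbh[jmask], jd[jmask], cfg)
        m_i = float(inner[species == sp_i].sum())
        m_h = float(inner[species != sp_i].sum())
        if species[j] == sp_i:
            out[0] += c_fj * m_i
            out[1] += c_fj * m_h
        else:
            out[2] += c_fj * m_i
            out[3] += c_fj * m_h
    return tuple(out)


def _contribution_matrices(x, y, dbh, cfg: CrowdingConfig):
    """Sparse matrices C and C2 over within-radius stem pairs.

    ``C[f, j] = dbh_j**a / d_fj**b`` is j's contribution to f's crowding;
    ``C2[f, j] = dbh_j**a / d_fj**(2b)`` carries the squared-distance kernel
    needed to subtract the focal stem from a transmitter's own crowding
    (``C[f, j] * C[j, f] = dbh_f**a * C2[f, j]``).
    """
    n = len(x)
    tree = cKDTree(np.column_stack([x, y]))
    pairs = tree.query_pairs(cfg.radius, output_type="ndarray")
    if len(pairs) == 0:
        empty = sparse.csr_matrix((n, n))
        return empty, empty.copy()
    a, b = pairs[:, 0], pairs[:, 1]
    d = np.hypot(x[a] - x[b], y[a] - y[b])
    d = np.maximum(d, cfg.min_distance)
    rows = np.concatenate([a, b])
    cols = np.concatenate([b, a])
    size_w = np.concatenate([dbh[b], dbh[a]]) ** cfg.size_exponent
    dist_w = np.concatenate([d, d]) ** cfg.distance_exponent
    C = sparse.csr_matrix((size_w / dist_w, (rows, cols)), shape=(n, n))
    C2 = sparse.csr_matrix((size_w / dist_w**2, (rows, cols)), shape=(n, n))
    return C, C2


def compute_crowding_table(
    stems: pd.DataFrame,
    x_extent: float,
    y_extent: float,
    cfg: CrowdingConfig | None = None,
    species: list[str] | None = None,
) -> pd.DataFrame:
    """All six crowding indices for every focal stem, with edge flags.

    Parameters
    ----------
    stems : pandas.DataFrame
        Census-1 main-stem table with columns ``treeID, stemID, sp, gx, gy,
        dbh`` (extra columns are ignored). All stems act as neighbours.
    x_extent, y_extent : float
        Plot dimensions (m); a stem is flagged ``interior`` iff it lies at
        least ``2 * cfg.radius`` from every plot edge, so that its
        transmitters' neighbourhoods are themselves untruncated.
    species : list of str, optional
        Focal species to profile (default: every species present). All stems
        still serve as neighbours and initiators regardless.

    Returns
    -------
    pandas.DataFrame
        One row per focal stem of a profiled species: identifiers, the six
        indices and the ``interior`` flag. Spatially accelerated with a
        k-d tree; results are identical to the exhaustive per-focal loops.
    """
    cfg = cfg or CrowdingConfig()
    x = stems["gx"].to_numpy(float)
    y = stems["gy"].to_numpy(float)
    dbh = stems["dbh"].to_numpy(float)
    sp = stems["sp"].to_numpy()

    C, C2 = _contribution_matrices(x, y, dbh, cfg)

    margin = 2 * cfg.radius
    interior = (
        (x >= margin) & (x <= x_extent - margin) & (y >= margin) & (y <= y_extent - margin)
    )

    targets = species if species is not None else sorted(pd.unique(sp))
    frames = []
    dbh_a = dbh**cfg.size_exponent
    for s in targets:
        ind = (sp == s).astype(float)
        focal_idx = np.flatnonzero(sp == s)
        if len(focal_idx) == 0:
            continue
        u_i = C @ ind  # crowding of every stem by species-s stems
        u_h = C @ (1.0 - ind)  # ... and by all other species
        n_i = u_i[focal_idx]
        n_h = u_h[focal_idx]

        Cf = C[focal_idx]
        n_ii = Cf @ (ind * u_i)
        n_ih = Cf @ (ind * u_h)
        n_hi = Cf @ ((1.0 - ind) * u_i)
        n_hh = Cf @ ((1.0 - ind) * u_h)
        if cfg.exclude_focal_from_neighbor_crowding:
            # remove the focal's own contribution to each transmitter's
            # species-i crowding: sum_j C[f,j] * C[j,f] over the right j
            C2f = C2[focal_idx]
            n_ii = n_ii - dbh_a[focal_idx] * (C2f @ ind)
            n_hi = n_hi - dbh_a[focal_idx] * (C2f @ (1.0 - ind))
        frames.append(
            pd.DataFrame(
                {
                    "treeID": stems["treeID"].to_numpy()[focal_idx]
                    if "treeID" in stems else focal_idx.astype(str),
                    "stemID": stems["stemID"].to_numpy()[focal_idx]
                    if "stemID" in stems else focal_idx.astype(str),
                    "sp": s,
                    "n_i": n_i,
                    "n_h": n_h,
                    "n_ii": np.maximum(n_ii, 0.0),
                    "n_ih": n_ih,
                    "n_hi": np.maximum(n_hi, 0.0),
                    "n_hh": n_hh,
                    "interior": interior[focal_idx],
                },
                index=focal_idx,
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["treeID", "stemID", "sp", *CROWDING_COLUMNS, "interior"]
        )
    out = pd.concat(frames).sort_index()
    if cfg.standardize:
        for col in CROWDING_COLUMNS:
            sd = out.groupby("sp")[col].transform("std")
            out[col] = np.where(sd > 0, out[col] / sd, out[col])
    return out
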