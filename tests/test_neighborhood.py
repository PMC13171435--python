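"""Crowding-index definitions, oracle equivalence and geometric invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hoiforest.neighborhood import (
    CROWDING_COLUMNS,
    CrowdingConfig,
    compute_crowding_table,
    higher_order_indices,
    neighbor_contribution,
    pairwise_indices,
)

from conftest import make_stems, random_stems


def brute_force_indices(stems, cfg, focal):
    """Literal triple-loop oracle over focal-transmitter-initiator triples."""
    x = stems["gx"].to_numpy()
    y = stems["gy"].to_numpy()
    dbh = stems["dbh"].to_numpy()
    sp = stems["sp"].to_numpy()
    n = len(stems)

    def dist(a, b):
        return max(np.hypot(x[a] - x[b], y[a] - y[b]), cfg.min_distance)

    def raw_dist(a, b):
        return np.hypot(x[a] - x[b], y[a] - y[b])

    def c(a, b):  # contribution of b to a
        return dbh[b] ** cfg.size_exponent / dist(a, b) ** cfg.distance_exponent

    n_i = n_h = 0.0
    hoi = dict(n_ii=0.0, n_ih=0.0, n_hi=0.0, n_hh=0.0)
    for j in range(n):
        if j == focal or raw_dist(focal, j) > cfg.radius:
            continue
        if sp[j] == sp[focal]:
            n_i += c(focal, j)
        else:
            n_h += c(focal, j)
        m_i = m_h = 0.0
        for k in range(n):
            if k == j or raw_dist(j, k) > cfg.radius:
                continue
            if cfg.exclude_focal_from_neighbor_crowding and k == focal:
                continue
            if sp[k] == sp[focal]:
                m_i += c(j, k)
            else:
                m_h += c(j, k)
        if sp[j] == sp[focal]:
            hoi["n_ii"] += c(focal, j) * m_i
            hoi["n_ih"] += c(focal, j) * m_h
        else:
            hoi["n_hi"] += c(focal, j) * m_i
            hoi["n_hh"] += c(focal, j) * m_h
    return n_i, n_h, hoi["n_ii"], hoi["n_ih"], hoi["n_hi"], hoi["n_hh"]


class TestNeighborContribution:
    @pytest.mark.parametrize(
        "dbh,d,exps,expected",
        [
            (10.0, 2.0, (1.0, 1.0), 5.0),
            (10.0, 0.01, (1.0, 1.0), 100.0),  # clamped to min_distance 0.1
            (10.0, 2.0, (2.0, 2.0), 25.0),
        ],
    )
    def test_kernel_values(self, dbh, d, exps, expected):
        cfg = CrowdingConfig(size_exponent=exps[0], distance_exponent=exps[1])
        assert neighbor_contribution(dbh, d, cfg) == pytest.approx(expected)

    def test_zero_distance_never_infinite(self):
        cfg = CrowdingConfig()
        assert np.isfinite(neighbor_contribution(10.0, 0.0, cfg))


class TestWorkedExamples:
    def test_isolated_focal_has_zero_indices(self):
        stems = make_stems([0, 50], [0, 50], [10, 10], ["a", "a"])
        cfg = CrowdingConfig(radius=10)
        args = (stems["gx"], stems["gy"], stems["dbh"], stems["sp"], cfg)
        assert pairwise_indices(0, *args) == (0.0, 0.0)
        assert higher_order_indices(0, *args) == (0.0, 0.0, 0.0, 0.0)

    def test_one_con_and_one_heterospecific_neighbor(self):
        stems = make_stems([0, 2, 4], [0, 0, 0], [5, 10, 20], ["a", "a", "b"])
        cfg = CrowdingConfig(radius=10)
        n_i, n_h = pairwise_indices(
            0, stems["gx"], stems["gy"], stems["dbh"], stems["sp"], cfg
        )
        assert n_i == pytest.approx(5.0)
        assert n_h == pytest.approx(5.0)

    def test_chain_outside_pair_radius_contributes_only_higher_order(self):
        # focal at origin; conspecific j at 2 m; conspecific k at 4 m is
        # outside the 3 m pair radius but 2 m from j, so it acts only as an
        # initiator: n_i = 10/2 = 5, n_ii = 5 * (20/2) = 50.
        stems = make_stems([0, 2, 4], [0, 0, 0], [5, 10, 20], ["a", "a", "a"])
        cfg = CrowdingConfig(radius=3)
        args = (stems["gx"], stems["gy"], stems["dbh"], stems["sp"], cfg)
        assert pairwise_indices(0, *args) == (pytest.approx(5.0), 0.0)
        n_ii, n_ih, n_hi, n_hh = higher_order_indices(0, *args)
        assert n_ii == pytest.approx(50.0)
        assert (n_ih, n_hi, n_hh) == (0.0, 0.0, 0.0)

    def test_lonely_transmitter_gives_zero_higher_order(self):
        # j's only neighbour is the focal itself, which is excluded from
        # transmitter crowding, so every higher-order index vanishes.
        stems = make_stems([0, 2], [0, 0], [5, 10], ["a", "a"])
        cfg = CrowdingConfig(radius=10)
        out = higher_order_indices(
            0, stems["gx"], stems["gy"], stems["dbh"], stems["sp"], cfg
        )
        assert out == (0.0, 0.0, 0.0, 0.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("exclude_focal", [True, False])
    def test_per_focal_functions_match_triple_loop(self, rng, exclude_focal):
        stems = random_stems(rng, 50, 40.0, n_species=2)
        cfg = CrowdingConfig(radius=12, exclude_focal_from_neighbor_crowding=exclude_focal)
        args = (stems["gx"], stems["gy"], stems["dbh"], stems["sp"], cfg)
        for focal in range(0, 50, 7):
            expected = brute_force_indices(stems, cfg, focal)
            got = pairwise_indices(focal, *args) + higher_order_indices(focal, *args)
            np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-12)

    def test_batch_table_matches_triple_loop(self, rng):
        stems = random_stems(rng, 60, 50.0, n_species=3)
        cfg = CrowdingConfig(radius=10)
        table = compute_crowding_table(stems, 50.0, 50.0, cfg).sort_index()
        for focal in range(0, 60, 11):
            expected = brute_force_indices(stems, cfg, focal)
            got = table.loc[focal, CROWDING_COLUMNS].to_numpy(float)
            np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-12)

    def test_batch_table_matches_oracle_on_larger_plot(self, rng):
        from hoiforest.validation import reference_crowding_table

        stems = random_stems(rng, 400, 80.0, n_species=4)
        cfg = CrowdingConfig(radius=9, size_exponent=2.0, distance_exponent=2.0)
        fast = compute_crowding_table(stems, 80.0, 80.0, cfg).sort_index()
        ref = reference_crowding_table(stems, 80.0, 80.0, cfg)
        for col in CROWDING_COLUMNS:
            a, b = fast[col].to_numpy(), ref[col].to_numpy()
            rel = np.abs(a - b) / np.maximum(np.maximum(np.abs(a), np.abs(b)), 1.0)
            assert rel.max() < 1e-10


class TestInvariances:
    @given(dx=st.floats(-20, 20), dy=st.floats(-20, 20))
    @settings(max_examples=20, deadline=None)
    def test_translation_invariance(self, dx, dy):
        rng = np.random.default_rng(99)
        stems = random_stems(rng, 40, 30.0, n_species=2)
        cfg = CrowdingConfig(radius=8)
        base = compute_crowding_table(stems, 30.0, 30.0, cfg).sort_index()
        moved = stems.copy()
        moved["gx"] += dx
        moved["gy"] += dy
        shifted = compute_crowding_table(
            moved, 30.0 + abs(dx) + 20, 30.0 + abs(dy) + 20, cfg
        ).sort_index()
        np.testing.assert_allclose(
            base[CROWDING_COLUMNS].to_numpy(),
            shifted[CROWDING_COLUMNS].to_numpy(),
            rtol=1e-9, atol=1e-9,
        )

    @given(theta=st.floats(0.05, 6.2))
    @settings(max_examples=15, deadline=None)
    def test_rotation_invariance(self, theta):
        rng = np.random.default_rng(7)
        stems = random_stems(rng, 35, 20.0, n_species=2)
        cfg = CrowdingConfig(radius=8)
        base = compute_crowding_table(stems, 1e4, 1e4, cfg).sort_index()
        rot = stems.copy()
        cx, cy = 10.0, 10.0
        dx, dy = stems["gx"] - cx, stems["gy"] - cy
        rot["gx"] = cx + np.cos(theta) * dx - np.sin(theta) * dy + 50
        rot["gy"] = cy + np.sin(theta) * dx + np.cos(theta) * dy + 50
        rotated = compute_crowding_table(rot, 1e4, 1e4, cfg).sort_index()
        np.testing.assert_allclose(
            base[CROWDING_COLUMNS].to_numpy(),
            rotated[CROWDING_COLUMNS].to_numpy(),
            rtol=1e-8, atol=1e-8,
        )

    @given(s=st.floats(0.5, 4.0))
    @settings(max_examples=15, deadline=None)
    def test_dbh_scaling_law(self, s):
        # pairwise indices scale as s**a, higher-order as s**(2a)
        rng = np.random.default_rng(3)
        stems = random_stems(rng, 40, 30.0, n_species=2)
        cfg = CrowdingConfig(radius=8)
        base = compute_crowding_table(stems, 30.0, 30.0, cfg).sort_index()
        scaled_stems = stems.copy()
        scaled_stems["dbh"] *= s
        scaled = compute_crowding_table(scaled_stems, 30.0, 30.0, cfg).sort_index()
        np.testing.assert_allclose(
            scaled[["n_i", "n_h"]].to_numpy(), s * base[["n_i", "n_h"]].to_numpy(),
            rtol=1e-9, atol=1e-12,
        )
        np.testing.assert_allclose(
            scaled[["n_ii", "n_ih", "n_hi", "n_hh"]].to_numpy(),
            s**2 * base[["n_ii", "n_ih", "n_hi", "n_hh"]].to_numpy(),
            rtol=1e-9, atol=1e-10,
        )

    def test_indices_nonnegative_and_zero_transmitter_implies_zero_hoi(self, rng):
        stems = random_stems(rng, 150, 60.0, n_species=4)
        cfg = CrowdingConfig(radius=7)
        table = compute_crowding_table(stems, 60.0, 60.0, cfg)
        assert (table[CROWDING_COLUMNS].to_numpy() >= 0).all()
        no_con = table["n_i"] == 0
        assert (table.loc[no_con, ["n_ii", "n_ih"]].to_numpy() == 0).all()
        no_het = table["n_h"] == 0
        assert (table.loc[no_het, ["n_hi", "n_hh"]].to_numpy() == 0).all()

    def test_adding_a_neighbor_never_decreases_its_indices(self, rng):
        stems = random_stems(rng, 60, 40.0, n_species=2)
        cfg = CrowdingConfig(radius=10)
        base = compute_crowding_table(stems, 40.0, 40.0, cfg).sort_index()
        extra = pd.concat(
            [stems, make_stems([20.0], [20.0], [15.0], ["s0"])], ignore_index=True
        )
        grown = compute_crowding_table(extra, 40.0, 40.0, cfg).sort_index().iloc[:60]
        eps = 1e-12
        assert (grown[CROWDING_COLUMNS].to_numpy() >= base[CROWDING_COLUMNS].to_numpy() - eps).all()

    def test_single_stem_plot(self):
        stems = make_stems([50.0], [50.0], [10.0], ["a"])
        table = compute_crowding_table(stems, 100.0, 100.0, CrowdingConfig(radius=10))
        assert len(table) == 1
        assert (table[CROWDING_COLUMNS].to_numpy() == 0).all()
        assert bool(table["interior"].iloc[0])

    def test_interior_flag_uses_double_radius_margin(self):
        stems = make_stems([19.9, 20.1], [50.0, 50.0], [5.0, 5.0], ["a", "b"])
        table = compute_crowding_table(stems, 100.0, 100.0, CrowdingConfig(radius=10))
        assert list(table.sort_index()["interior"]) == [False, True]

    def test_standardize_divides_by_within_species_sd(self, rng):
        stems = random_stems(rng, 80, 40.0, n_species=2)
        raw = compute_crowding_table(stems, 40.0, 40.0, CrowdingConfig(radius=10)).sort_index()
        std = compute_crowding_table(
            stems, 40.0, 40.0, CrowdingConfig(radius=10, standardize=True)
        ).sort_index()
        for col in CROWDING_COLUMNS:
            sd = raw.groupby("sp")[col].transform("std").to_numpy()
            expected = np.where(sd > 0, raw[col].to_numpy() / sd, raw[col].to_numpy())
            np.testing.assert_allclose(std[col].to_numpy(), expected, rtol=1e-10)
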