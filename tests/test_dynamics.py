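"""Frame-to-frame linking, transition matrices, velocities, vector fields."""

import numpy as np
import pandas as pd
import pytest

from upside import (LinkageSet, MarkovModel, SceneSpec, link_pairs,
                    population_dynamics, simulate_tracks, suggest_d0,
                    transition_matrix, transition_vector_field, velocities)
from .oracles import brute_force_links, random_frame_pair


def _table(rows):
    return pd.DataFrame(rows, columns=["frame", "cell_id", "y", "x"])


class TestLinkPairs:
    def test_single_moving_cell(self):
        dets = _table([(0, 0, 10.0, 10.0), (1, 0, 13.0, 12.6)])
        ls = link_pairs(dets, d0=5.0, d1=10.0)
        assert len(ls) == 1
        assert ls.links.iloc[0]["distance_px"] == pytest.approx(
            np.hypot(3.0, 2.6))

    def test_isolation_rule_excludes_crowded_source(self):
        dets = _table([(0, 0, 10.0, 10.0), (0, 1, 10.0, 12.0),  # 2 px apart
                       (1, 2, 11.0, 10.0), (1, 3, 11.0, 12.0)])
        ls = link_pairs(dets, d0=4.0, d1=10.0)
        assert len(ls) == 0

    def test_max_travel_rule(self):
        dets = _table([(0, 0, 10.0, 10.0), (1, 0, 10.0, 40.0)])
        assert len(link_pairs(dets, d0=5.0, d1=20.0)) == 0
        assert len(link_pairs(dets, d0=5.0, d1=40.0)) == 1

    def test_collision_keeps_closer_source(self):
        dets = _table([(0, 0, 10.0, 10.0), (0, 1, 10.0, 30.0),
                       (1, 9, 10.0, 18.0)])
        ls = link_pairs(dets, d0=15.0, d1=15.0)
        assert len(ls) == 1
        assert ls.links.iloc[0]["src_id"] == 0   # 8 px beats 12 px

    def test_single_frame_empty(self):
        ls = link_pairs(_table([(0, 0, 5.0, 5.0)]), d0=3.0, d1=5.0)
        assert len(ls) == 0

    def test_injectivity_both_roles(self):
        rng = np.random.default_rng(0)
        dets = random_frame_pair(rng, n_max=150)
        ls = link_pairs(dets, d0=10.0, d1=25.0)
        assert ls.links["src_id"].is_unique
        assert ls.links["dst_id"].is_unique

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_pseudocode(self, seed):
        rng = np.random.default_rng(seed)
        dets = random_frame_pair(rng, n_max=300)
        d0 = float(rng.uniform(5, 25))
        d1 = float(rng.uniform(5, 40))
        ls = link_pairs(dets, d0=d0, d1=d1)
        got = {(int(r.frame), int(r.src_id), int(r.dst_id))
               for r in ls.links.itertuples()}
        frames = {t: [(int(r.cell_id), float(r.y), float(r.x))
                      for r in sub.itertuples()]
                  for t, sub in dets.groupby("frame")}
        assert got == brute_force_links(frames, d0, d1)

    def test_suggest_d0(self):
        dets = _table([(0, 0, 0.0, 0.0), (0, 1, 0.0, 10.0)])
        assert suggest_d0(dets) == pytest.approx(15.0)

    def test_invalid_radii(self):
        with pytest.raises(ValueError):
            link_pairs(_table([(0, 0, 1.0, 1.0)]), d0=0.0, d1=5.0)


class TestTransitionMatrix:
    def test_hand_counts(self):
        links = pd.DataFrame({"frame": [0, 0, 0, 0],
                              "src_id": [0, 1, 2, 3],
                              "dst_id": [0, 1, 2, 3],
                              "distance_px": [1.0] * 4})
        ls = LinkageSet(links, d0=5.0, d1=5.0)
        labels = {(0, 0): 0, (0, 1): 0, (0, 2): 0, (0, 3): 0,
                  (1, 0): 0, (1, 1): 0, (1, 2): 0, (1, 3): 1}
        tm = transition_matrix(ls, labels, n_clusters=2)
        assert tm.P[0, 1] == pytest.approx(0.25)
        assert tm.P[0, 0] == pytest.approx(0.75)
        assert 1 in tm.undefined_rows

    def test_identity_dynamics(self):
        scene = SceneSpec(frame_shape=(600, 600), n_cells=20,
                          exclusion_radius=60.0, step_sd=(1.0, 1.0),
                          border_margin=30.0)
        tracks = simulate_tracks(scene, MarkovModel(np.eye(2)), 20, seed=1)
        ls = link_pairs(tracks[["frame", "cell_id", "y", "x"]],
                        d0=12.0, d1=10.0)
        labels = tracks.rename(columns={"state": "cluster"})[
            ["frame", "cell_id", "cluster"]]
        tm = transition_matrix(ls, labels, n_clusters=2)
        assert np.allclose(tm.P, np.eye(2))

    def test_row_stochastic_and_reversal_symmetry(self):
        rng = np.random.default_rng(2)
        P = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.2, 0.2, 0.6]])
        scene = SceneSpec(frame_shape=(800, 800), n_cells=40,
                          exclusion_radius=55.0, step_sd=(1.5,) * 3,
                          border_margin=30.0)
        tracks = simulate_tracks(scene, MarkovModel(P), 60, seed=2)
        dets = tracks[["frame", "cell_id", "y", "x"]]
        labels = tracks.rename(columns={"state": "cluster"})[
            ["frame", "cell_id", "cluster"]]
        ls = link_pairs(dets, d0=12.0, d1=12.0)
        tm = transition_matrix(ls, labels, n_clusters=3)
        assert np.allclose(tm.P.sum(axis=1), 1.0, atol=1e-12)
        # reversed movie: transition counts are the transpose
        rev = tracks.copy()
        rev["frame"] = rev["frame"].max() - rev["frame"]
        ls_rev = link_pairs(rev[["frame", "cell_id", "y", "x"]],
                            d0=12.0, d1=12.0)
        labels_rev = rev.rename(columns={"state": "cluster"})[
            ["frame", "cell_id", "cluster"]]
        tm_rev = transition_matrix(ls_rev, labels_rev, n_clusters=3)
        assert np.array_equal(tm_rev.counts, tm.counts.T)

    def test_unlabeled_links_warn(self):
        links = pd.DataFrame({"frame": [0], "src_id": [0], "dst_id": [0],
                              "distance_px": [1.0]})
        ls = LinkageSet(links, d0=1.0, d1=1.0)
        with pytest.warns(UserWarning):
            tm = transition_matrix(ls, {(0, 0): 0}, n_clusters=1)
        assert tm.counts.sum() == 0


class TestVelocities:
    def test_unit_conversion(self):
        links = pd.DataFrame({"frame": [0], "src_id": [0], "dst_id": [0],
                              "distance_px": [12.0]})
        ls = LinkageSet(links, d0=1.0, d1=20.0)
        per_link, _ = velocities(ls, minutes_per_frame=3.0, um_per_px=0.5)
        assert per_link["speed"].iloc[0] == pytest.approx(2.0)  # 6 um / 3 min

    def test_stationary_cells_near_zero(self):
        scene = SceneSpec(frame_shape=(300, 300), n_cells=5, step_sd=(0.0,),
                          exclusion_radius=60.0)
        tracks = simulate_tracks(scene, MarkovModel(np.eye(1)), 10, seed=3)
        ls = link_pairs(tracks[["frame", "cell_id", "y", "x"]],
                        d0=20.0, d1=5.0)
        per_link, _ = velocities(ls, 3.0)
        assert per_link["speed"].max() < 1e-9

    def test_planted_step_ratio_recovered(self):
        scene = SceneSpec(frame_shape=(900, 900), n_cells=50,
                          exclusion_radius=60.0, step_sd=(1.0, 3.0),
                          border_margin=30.0)
        tracks = simulate_tracks(scene, MarkovModel(np.eye(2)), 80, seed=4)
        ls = link_pairs(tracks[["frame", "cell_id", "y", "x"]],
                        d0=15.0, d1=18.0)
        labels = tracks.rename(columns={"state": "cluster"})[
            ["frame", "cell_id", "cluster"]]
        _, summary = velocities(ls, 3.0, labels=labels)
        ratio = summary.loc[summary["cluster"] == 1, "mean"].iloc[0] \
            / summary.loc[summary["cluster"] == 0, "mean"].iloc[0]
        assert ratio == pytest.approx(3.0, abs=0.3)

    def test_zero_interval_rejected(self):
        ls = LinkageSet(pd.DataFrame(columns=["frame", "src_id", "dst_id",
                                              "distance_px"]), 1.0, 1.0)
        with pytest.raises(ValueError):
            velocities(ls, 0.0)


class TestVectorField:
    def test_identity_dynamics_zero_vectors(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 10, (200, 2))
        field = transition_vector_field(pts, pts, grid_size=4)
        occupied = field.dropna()
        assert np.allclose(occupied[["dx", "dy"]], 0.0)
        assert np.allclose(occupied["magnitude"], 0.0)

    def test_planted_flow_points_toward_target(self):
        rng = np.random.default_rng(6)
        start = rng.normal([0.0, 0.0], 1.0, (300, 2))
        drift = np.array([5.0, 2.0])
        end = start + drift + rng.normal(0, 0.3, (300, 2))
        field = transition_vector_field(start, end, grid_size=5)
        occ = field.dropna()
        dots = occ[["dx", "dy"]].to_numpy() @ (drift / np.linalg.norm(drift))
        assert (dots > 0).mean() > 0.8

    def test_count_weighted_conservation(self):
        rng = np.random.default_rng(7)
        start = rng.uniform(0, 10, (150, 2))
        end = start + rng.normal(0, 1, (150, 2))
        field = transition_vector_field(start, end, grid_size=6)
        occ = field.dropna()
        total = (occ[["dx", "dy"]].to_numpy()
                 * occ["n"].to_numpy()[:, None]).sum(axis=0)
        assert np.allclose(total, (end - start).sum(axis=0))


class TestPopulationDynamics:
    def _state_table(self, rng, p_by_condition, n=400, frames=20):
        rows = []
        for cond, p in p_by_condition.items():
            for i in range(n):
                for t in range(frames):
                    rows.append((t, rng.choice(len(p), p=p), cond))
        return pd.DataFrame(rows, columns=["frame", "cluster", "condition"])

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(8)
        df = self._state_table(rng, {"ctrl": [0.5, 0.5]})
        fractions, test = population_dynamics(df)
        assert np.allclose(fractions.sum(axis=1), 1.0, atol=1e-12)
        assert test is None

    def test_identical_distributions_high_p(self):
        rng = np.random.default_rng(9)
        df = self._state_table(rng, {"a": [0.5, 0.5], "b": [0.5, 0.5]})
        _, test = population_dynamics(df)
        assert test["p_value"] > 0.05

    def test_chi_square_against_hand_sum(self):
        from scipy.stats import chi2

        counts = np.array([[30, 10], [10, 30]])
        # direct sum((O-E)^2/E) oracle
        row, col = counts.sum(1, keepdims=True), counts.sum(0, keepdims=True)
        expected = row * col / counts.sum()
        stat_oracle = ((counts - expected) ** 2 / expected).sum()
        df = pd.DataFrame(
            [(19, c, cond) for cond, row_ in zip("ab", counts)
             for c, k in enumerate(row_) for _ in range(k)],
            columns=["frame", "cluster", "condition"])
        _, test = population_dynamics(df)
        assert test["statistic"] == pytest.approx(stat_oracle)
        assert test["p_value"] == pytest.approx(
            chi2.sf(stat_oracle, 1))

    def test_different_distributions_detected(self):
        rng = np.random.default_rng(10)
        df = self._state_table(rng, {"a": [0.7, 0.3], "b": [0.3, 0.7]})
        _, test = population_dynamics(df)
        assert test["p_value"] < 0.001
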