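"""Neighbor graph and the permutation interaction/avoidance test."""

import numpy as np
import pandas as pd
import pytest

from imcspatial import spatial
from imcspatial.exceptions import ValidationError
from imcspatial.spatial import (
    build_graph,
    cohort_interaction_summary,
    interaction_test,
    results_to_frame,
)


def cells_frame(xy, ids=None):
    xy = np.asarray(xy, dtype=float)
    if ids is None:
        ids = np.arange(1, len(xy) + 1)
    return pd.DataFrame({"cell_id": ids, "x": xy[:, 0], "y": xy[:, 1]})


class TestBuildGraph:
    def test_edge_within_radius(self):
        g = build_graph(cells_frame([(0, 0), (10, 0)]), radius_um=15)
        assert g.n_edges == 1

    def test_no_edge_beyond_radius(self):
        g = build_graph(cells_frame([(0, 0), (10, 0)]), radius_um=5)
        assert g.n_edges == 0

    def test_um_conversion(self):
        # 10 px apart at 2 um/px = 20 um
        g = build_graph(cells_frame([(0, 0), (10, 0)]), radius_um=15,
                        um_per_px=2.0)
        assert g.n_edges == 0

    def test_brute_force_oracle_300_cells(self):
        rng = np.random.default_rng(42)
        xy = rng.uniform(0, 500, size=(300, 2))
        cells = cells_frame(xy)
        g = build_graph(cells, radius_um=25.0)
        oracle = set()
        for i in range(300):
            for j in range(i + 1, 300):
                if np.hypot(*(xy[i] - xy[j])) <= 25.0:
                    oracle.add((i + 1, j + 1))
        assert g.edge_id_set() == oracle

    def test_row_order_invariant(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 100, size=(50, 2))
        cells = cells_frame(xy)
        shuffled = cells.sample(frac=1.0, random_state=7).reset_index(drop=True)
        g1 = build_graph(cells, 20.0)
        g2 = build_graph(shuffled, 20.0)
        assert g1.edge_id_set() == g2.edge_id_set()

    def test_no_self_edges(self):
        g = build_graph(cells_frame([(0, 0), (1, 0), (0, 1)]), 10.0)
        assert all(i != j for i, j in g.edges)


def naive_interaction_test(graph, lineages, n_perm, seed, min_cells=10):
    """Independent shuffle-and-recount oracle (explicit loops)."""
    ids = graph.cell_ids
    labels = [lineages[int(c)] for c in ids]
    nbrs = {i: [] for i in range(len(ids))}
    for i, j in graph.edges:
        nbrs[int(i)].append(int(j))
        nbrs[int(j)].append(int(i))
    types = sorted(set(labels))

    def stat(lab):
        out = {}
        for a in types:
            a_nodes = [i for i, l in enumerate(lab) if l == a]
            for b in types:
                total = sum(sum(1 for j in nbrs[i] if lab[j] == b)
                            for i in a_nodes)
                out[(a, b)] = total / len(a_nodes) if a_nodes else np.nan
        return out

    obs = stat(labels)
    rng = np.random.default_rng(seed)
    null = []
    arr = np.array(labels, dtype=object)
    for _ in range(n_perm):
        perm = rng.permutation(len(ids))
        null.append(stat(list(arr[perm])))
    counts = {t: labels.count(t) for t in types}
    res = {}
    for pair in obs:
        a, b = pair
        if counts[a] < min_cells or counts[b] < min_cells:
            res[pair] = dict(p_int=1.0, p_avd=1.0, z=0.0, obs=obs[pair])
            continue
        vals = np.array([nl[pair] for nl in null])
        p_int = (1 + int((vals >= obs[pair]).sum())) / (1 + n_perm)
        p_avd = (1 + int((vals <= obs[pair]).sum())) / (1 + n_perm)
        sd = vals.std()
        z = (obs[pair] - vals.mean()) / sd if sd > 0 else 0.0
        res[pair] = dict(p_int=p_int, p_avd=p_avd, z=z, obs=obs[pair])
    return res


def random_labeled_cells(n, seed, types=("A", "B", "C")):
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, 300, size=(n, 2))
    labels = rng.choice(types, size=n)
    cells = cells_frame(xy)
    return cells, dict(zip(cells["cell_id"], labels))


class TestInteractionTest:
    def test_single_lineage_all_invalid_cross_pairs(self):
        cells, _ = random_labeled_cells(30, 0)
        lineages = {int(c): "A" for c in cells["cell_id"]}
        res = interaction_test(build_graph(cells, 30.0), lineages,
                               n_perm=100, seed=1)
        assert len(res) == 1  # only (A, A)
        assert res[0].valid  # 30 >= min_cells

    def test_min_cells_marks_invalid(self):
        cells, lineages = random_labeled_cells(30, 2)
        # make type C rare
        for cid in list(lineages)[:28]:
            lineages[cid] = "A"
        res = interaction_test(build_graph(cells, 30.0), lineages,
                               n_perm=100, min_cells=5, seed=1)
        for r in res:
            if "C" in (r.type_a, r.type_b) or "B" in (r.type_a, r.type_b):
                assert not r.valid
                assert r.p_interaction == 1.0 and r.z == 0.0

    def test_p_values_in_half_open_unit_interval(self):
        cells, lineages = random_labeled_cells(100, 3)
        res = interaction_test(build_graph(cells, 25.0), lineages,
                               n_perm=100, seed=5)
        for r in res:
            assert 0 < r.p_interaction <= 1
            assert 0 < r.p_avoidance <= 1

    def test_null_preserves_lineage_multiset(self):
        cells, lineages = random_labeled_cells(60, 4)
        # check_null asserts multiset conservation on every permutation
        interaction_test(build_graph(cells, 25.0), lineages,
                         n_perm=100, seed=6, check_null=True)

    def test_matches_naive_oracle_exactly(self):
        """Same seed, graphs <= 200 nodes: identical p-values and z."""
        for seed in (0, 1):
            cells, lineages = random_labeled_cells(150, 10 + seed)
            g = build_graph(cells, 25.0)
            res = interaction_test(g, lineages, n_perm=200, seed=seed,
                                   min_cells=10)
            oracle = naive_interaction_test(g, lineages, 200, seed,
                                            min_cells=10)
            for r in res:
                o = oracle[(r.type_a, r.type_b)]
                assert r.p_interaction == o["p_int"]
                assert r.p_avoidance == o["p_avd"]
                assert r.z == pytest.approx(o["z"], abs=1e-9)
                assert r.observed == pytest.approx(o["obs"], abs=1e-9)

    def test_invariant_under_cell_relabeling(self):
        cells, lineages = random_labeled_cells(80, 7)
        g1 = build_graph(cells, 25.0)
        res1 = interaction_test(g1, lineages, n_perm=100, seed=3)
        # shift all ids by 1000; same geometry and labels
        cells2 = cells.copy()
        cells2["cell_id"] = cells2["cell_id"] + 1000
        lineages2 = {cid + 1000: lin for cid, lin in lineages.items()}
        res2 = interaction_test(build_graph(cells2, 25.0), lineages2,
                                n_perm=100, seed=3)
        for r1, r2 in zip(res1, res2):
            assert r1.z == pytest.approx(r2.z, abs=1e-12)

    def test_undefined_lineage_rejected(self):
        cells, lineages = random_labeled_cells(30, 8)
        lineages.pop(1)
        with pytest.raises(ValidationError, match="undefined"):
            interaction_test(build_graph(cells, 25.0), lineages,
                             n_perm=100, seed=0)

    def test_too_few_permutations_rejected(self):
        cells, lineages = random_labeled_cells(30, 9)
        with pytest.raises(ValidationError, match="n_perm"):
            interaction_test(build_graph(cells, 25.0), lineages,
                             n_perm=10, seed=0)


class TestCohortSummary:
    def _results(self, z, q=1.0):
        return pd.DataFrame([{
            "type_a": "A", "type_b": "B", "observed": 1.0, "null_mean": 1.0,
            "null_sd": 1.0, "z": z, "p_interaction": 0.5, "p_avoidance": 0.5,
            "q_interaction": q, "q_avoidance": q, "n_a": 20, "n_b": 20,
            "n_perm": 100, "valid": True,
        }])

    def test_identical_groups_zero_difference(self):
        res = {"p1_primary": self._results(1.5),
               "p1_recurrent": self._results(1.5)}
        out = cohort_interaction_summary(
            res, {"p1": ("p1_primary", "p1_recurrent")})
        assert out["paired_z_diff"].iloc[0] == 0.0

    def test_recurrent_only_attraction_positive_diff(self):
        res = {"p1_primary": self._results(0.1),
               "p1_recurrent": self._results(4.0, q=0.01),
               "p2_primary": self._results(-0.2),
               "p2_recurrent": self._results(3.5, q=0.01)}
        out = cohort_interaction_summary(
            res, {"p1": ("p1_primary", "p1_recurrent"),
                  "p2": ("p2_primary", "p2_recurrent")})
        assert out["paired_z_diff"].iloc[0] > 0
        assert out["n_significant_recurrent"].iloc[0] == 2
        assert out["n_significant_primary"].iloc[0] == 0

    def test_missing_sample_rejected(self):
        res = {"p1_primary": self._results(1.0)}
        with pytest.raises(ValidationError, match="p1"):
            cohort_interaction_summary(
                res, {"p1": ("p1_primary", "p1_recurrent")})

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValidationError, match="pairs"):
            cohort_interaction_summary({}, {})


class TestRecurrentOnlyAttraction:
    def test_positive_paired_z_difference_under_generator(self):
        """Attraction injected only at relapse raises the paired z diff."""
        from imcspatial import synth

        base = synth.SimulationConfig(
            field_size_px=(500, 500), n_cells=300, noise_model="none",
            psf_sigma_px=0.0)
        samples = synth.simulate_cohort(
            base, n_pairs=2, seed=3,
            recurrent_overrides={
                "placement": "paired_attraction",
                "attraction_pairs": [("monocyte", "cytotoxic T cell", 0.9)],
            })
        results = {}
        for s in samples:
            cids = sorted(s.truth.true_centroids)
            cells = pd.DataFrame({
                "cell_id": cids,
                "x": [s.truth.true_centroids[c][0] for c in cids],
                "y": [s.truth.true_centroids[c][1] for c in cids],
            })
            g = build_graph(cells, 20.0)
            res = interaction_test(g, s.truth.true_lineage, n_perm=200,
                                   seed=4)
            results[s.sample_id] = results_to_frame(res)
        pairs = {"pair1": ("pair1_primary", "pair1_recurrent"),
                 "pair2": ("pair2_primary", "pair2_recurrent")}
        summary = cohort_interaction_summary(results, pairs)
        row = summary[(summary.type_a == "monocyte")
                      & (summary.type_b == "cytotoxic T cell")]
        assert row["paired_z_diff"].iloc[0] > 0


class TestResultsFrame:
    def test_one_row_per_ordered_pair(self):
        cells, lineages = random_labeled_cells(90, 11)
        res = interaction_test(build_graph(cells, 25.0), lineages,
                               n_perm=100, seed=2)
        df = results_to_frame(res)
        n_types = len(set(lineages.values()))
        assert len(df) == n_types ** 2
        assert set(zip(df.type_a, df.type_b)) == {
            (a, b) for a in set(lineages.values())
            for b in set(lineages.values())}
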