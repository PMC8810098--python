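"""Pearson edges, top-correlate selection and deterministic cluster order."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lncnet.config import AnalysisConfig
from lncnet.coexpression import (build_edges, cluster_order, pearson_with_p,
                                 top_correlates)
from lncnet.data_model import ExpressionMatrix
from lncnet.errors import DegenerateInputError
from lncnet.simulate import (SimulationConfig, simulate_expression,
                             simulate_genome_annotation)


class TestPearson:
    def test_hand_computed_example(self):
        # cov 4, sx^2 = sy^2 = 5 -> r = 0.8; t = 1.886 on 2 df -> p = 0.2
        r, p = pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, rel=1e-12)
        assert p == pytest.approx(0.2, rel=1e-9)

    def test_perfect_correlation(self):
        x = [1.0, 2.0, 5.0]
        assert pearson_with_p(x, x) == (1.0, 0.0)
        assert pearson_with_p(x, [-v for v in x]) == (-1.0, 0.0)

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_with_p([1, 1, 1], [1, 2, 3])

    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=8, unique=True),
           st.floats(0.1, 3.0), st.floats(-2.0, 2.0))
    def test_symmetry_and_affine_invariance(self, x, slope, shift):
        rng = np.random.default_rng(0)
        y = list(rng.permutation(x))
        if np.ptp(y) == 0:
            return
        r_xy, p_xy = pearson_with_p(x, y)
        r_yx, p_yx = pearson_with_p(y, x)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        assert p_xy == pytest.approx(p_yx, abs=1e-12)
        r_scaled, p_scaled = pearson_with_p([slope * v + shift for v in x], y)
        assert r_scaled == pytest.approx(r_xy, abs=1e-9)
        assert p_scaled == pytest.approx(p_xy, abs=1e-9)


def _matrix_from(values: dict[str, list[float]], n_case: int) -> ExpressionMatrix:
    df = pd.DataFrame(values).T
    n = df.shape[1]
    df.columns = [f"s{i}" for i in range(n)]
    groups = pd.Series(["case"] * n_case + ["control"] * (n - n_case),
                       index=df.columns)
    return ExpressionMatrix(df, groups)


def _annot_for(probes, biotypes):
    return pd.DataFrame(
        {"gene_symbol": [f"g_{p}" for p in probes],
         "biotype": biotypes,
         "chrom": ["c"] * len(probes), "start": [1] * len(probes),
         "end": [9] * len(probes), "strand": ["+"] * len(probes)},
        index=pd.Index(probes, name="probe_id"))


class TestBuildEdges:
    def test_edge_count_excludes_degenerate_probes(self):
        matrix = _matrix_from({
            "L1": [1, 2, 3, 4], "M1": [4, 3, 2, 1],
            "M2": [2, 2, 2, 2], "M3": [1, 3, 2, 4]}, 2)
        annot = _annot_for(["L1", "M1", "M2", "M3"],
                           ["lncRNA", "mRNA", "mRNA", "mRNA"])
        edges = build_edges(["L1"], matrix, annot)
        assert len(edges) == 2  # M2 constant -> skipped
        assert set(edges["mrna_id"]) == {"M1", "M3"}

    def test_thresholds_inclusive_at_equality(self):
        # r = 0.8 exactly, p = 0.2 exactly: passes iff both bounds inclusive
        matrix = _matrix_from({"L1": [1, 2, 3, 4], "M1": [1, 3, 2, 4]}, 2)
        annot = _annot_for(["L1", "M1"], ["lncRNA", "mRNA"])
        cfg = AnalysisConfig(corr_r_threshold=0.8, corr_p_threshold=0.2)
        edges = build_edges(["L1"], matrix, annot, cfg)
        assert edges["r"].iloc[0] == pytest.approx(0.8)
        assert bool(edges["passes"].iloc[0])
        stricter = AnalysisConfig(corr_r_threshold=0.8001, corr_p_threshold=0.2)
        assert not build_edges(["L1"], matrix, annot, stricter)["passes"].iloc[0]

    def test_bh_mode_gates_on_q(self):
        cfg = SimulationConfig(n_mrna=60, n_lncrna=2, de_fraction=0,
                               module_spec=((1, 10, 0.9),), cis_spec=(),
                               plant_de_on_structures=False, seed=3)
        matrix, truth = simulate_expression(cfg)
        annot = simulate_genome_annotation(cfg)
        hub = truth.hub_probes()[0]
        raw = build_edges([hub], matrix, annot, AnalysisConfig(corr_adjust="raw"))
        bh = build_edges([hub], matrix, annot, AnalysisConfig(corr_adjust="bh"))
        assert (bh["q_value"] >= bh["p_value"] - 1e-15).all()
        assert bh["passes"].sum() <= raw["passes"].sum()


class TestTopCorrelates:
    def _edges(self, rs, passes=None):
        n = len(rs)
        return pd.DataFrame({
            "lncrna_id": ["L1"] * n,
            "mrna_id": [f"M{i:02d}" for i in range(n)],
            "r": rs, "p_value": [0.01] * n, "q_value": [0.01] * n,
            "n": 12, "passes": passes if passes is not None else [True] * n})

    def test_selection_size_and_order(self, rng):
        rs = rng.uniform(-1, 1, size=40)
        out = top_correlates(self._edges(list(rs)), "L1", k=30)
        assert len(out) == 30
        ordered = sorted(np.abs(rs), reverse=True)[:30]
        got = [abs(rs[int(m[1:])]) for m in out]
        assert got == pytest.approx(ordered)

    def test_small_input_returned_whole(self):
        assert len(top_correlates(self._edges([0.5] * 12), "L1", k=30)) == 12

    def test_tie_broken_by_id(self):
        out = top_correlates(self._edges([0.9, -0.9, 0.9]), "L1", k=3)
        assert out == ["M00", "M01", "M02"]  # |r| equal: lexicographic ids

    def test_passing_preferred_over_stronger_nonpassing(self):
        edges = self._edges([0.99, 0.85], passes=[False, True])
        assert top_correlates(edges, "L1", k=1) == ["M01"]

    def test_unknown_lncrna(self):
        with pytest.raises(KeyError):
            top_correlates(self._edges([0.5]), "nope")


def brute_average_linkage(dist: np.ndarray):
    """O(n^3) average linkage directly from the definition (mean pair distance)."""
    n = dist.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                d = np.mean([dist[x, y] for x in clusters[a]
                             for y in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(heights)


class TestClusterOrder:
    def test_identical_pair_merges_first(self):
        values = pd.DataFrame([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]],
                              index=["a", "b", "c"], dtype=float)
        order = cluster_order(values)
        assert order.linkage[0, 2] == pytest.approx(0.0)
        assert order.item_ids[:2] == ["a", "b"]

    def test_two_items_base_case(self):
        values = pd.DataFrame([[1, 2, 3], [3, 1, 2]], index=["x", "y"],
                              dtype=float)
        assert cluster_order(values).item_ids == ["x", "y"]

    def test_heights_match_brute_force_oracle(self, rng):
        for trial in range(5):
            n = 6 + trial % 3
            values = pd.DataFrame(rng.normal(size=(n, 10)),
                                  index=[f"i{j}" for j in range(n)])
            order = cluster_order(values)
            dist = 1.0 - np.corrcoef(values.to_numpy())
            np.fill_diagonal(dist, 0.0)
            expected = brute_average_linkage(dist)
            assert np.allclose(np.sort(order.linkage[:, 2]),
                               np.sort(expected), atol=1e-10)

    def test_permutation_leaves_merge_structure_unchanged(self, rng):
        values = pd.DataFrame(rng.normal(size=(6, 12)),
                              index=[f"i{j}" for j in range(6)])
        base = cluster_order(values)
        perm = values.iloc[[3, 0, 5, 1, 4, 2]]
        shuffled = cluster_order(perm)
        assert np.allclose(np.sort(base.linkage[:, 2]),
                           np.sort(shuffled.linkage[:, 2]), atol=1e-10)
        # same items, deterministic permutation of the input set
        assert sorted(base.item_ids) == sorted(shuffled.item_ids)

    def test_constant_profile_gets_maximal_distance(self, caplog):
        values = pd.DataFrame([[1, 2, 3, 4], [2, 4, 6, 8], [5, 5, 5, 5]],
                              index=["a", "b", "flat"], dtype=float)
        with caplog.at_level("WARNING"):
            order = cluster_order(values)
        assert "constant" in caplog.text
        assert order.item_ids[-1] == "flat"
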