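import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergmix.graph_core import (
    EspDistribution,
    GraphValidationError,
    NodeAttributeTable,
    compute_statistics,
    density,
    esp_distribution,
    gwesp_from_esp,
    gwesp_statistic,
    mixing_counts,
    read_adjacency,
    read_attributes,
    validate_graph,
    write_adjacency,
    write_attributes,
)
from ergmix.model import ModelSpec

from .conftest import make_attrs, make_graph, random_graph


class TestValidateGraph:
    def test_accepts_154_node_hollow_symmetric(self, rng):
        a = (rng.random((154, 154)) < 0.1).astype(int)
        a = np.triu(a, 1)
        g = validate_graph(a + a.T)
        assert g.n_nodes == 154

    def test_asymmetric_entry_rejected(self):
        a = np.zeros((4, 4), dtype=int)
        a[1, 2] = 1  # no mirror entry
        with pytest.raises(GraphValidationError, match=r"a\[1,2\]"):
            validate_graph(a)

    def test_self_loop_rejected(self):
        a = np.zeros((4, 4), dtype=int)
        a[3, 3] = 1
        with pytest.raises(GraphValidationError, match="self-loop"):
            validate_graph(a)

    def test_non_binary_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.5
        with pytest.raises(GraphValidationError, match="non-binary"):
            validate_graph(a)

    def test_non_square_rejected(self):
        with pytest.raises(GraphValidationError, match="square"):
            validate_graph(np.zeros((3, 4)))


class TestDensity:
    def test_complete_graph(self, k4):
        assert density(k4) == 1.0

    def test_empty_graph(self):
        assert density(validate_graph(np.zeros((6, 6), dtype=int))) == 0.0

    def test_five_nodes_four_edges(self):
        g = make_graph([(0, 1), (1, 2), (2, 3), (3, 4)], 5)
        assert density(g) == pytest.approx(0.4)

    def test_single_node_undefined(self):
        with pytest.raises(GraphValidationError):
            density(validate_graph(np.zeros((1, 1), dtype=int)))


class TestEspDistribution:
    def test_triangle(self, triangle):
        assert esp_distribution(triangle).counts == {1: 3}

    def test_star_leaves_share_nothing(self, star4):
        assert esp_distribution(star4).counts == {0: 3}

    def test_complete_graph(self, k4):
        assert esp_distribution(k4).counts == {2: 6}

    @given(st.integers(0, 2**40 - 1), st.integers(5, 10))
    @settings(max_examples=60, deadline=None)
    def test_esp_conserves_edge_count(self, bits, n):
        rng = np.random.default_rng(bits)
        g = random_graph(rng, n, 0.4)
        assert esp_distribution(g).n_edges == g.n_edges


class TestGwesp:
    @pytest.mark.parametrize("lam", [0.0, 0.3, 0.45, 1.0, 2.5])
    def test_all_single_shared_partner(self, lam):
        # e^lam * (1 - (1 - e^-lam)) * 3 == 3 for every decay
        esp = EspDistribution({1: 3})
        assert gwesp_from_esp(esp, lam) == pytest.approx(3.0)

    def test_empty_distribution(self):
        assert gwesp_from_esp(EspDistribution({}), 0.7) == 0.0

    def test_negative_decay_rejected(self):
        with pytest.raises(ValueError):
            gwesp_from_esp(EspDistribution({1: 1}), -0.1)
        with pytest.raises(ValueError):
            gwesp_statistic(make_graph([(0, 1)], 3), -1.0)

    def test_published_fixed_decay_value(self):
        # observed ESP histogram of a 1,796-edge graph; the 7 edges beyond
        # the esp14 tail are placed at shared-partner count 15
        counts = dict(
            zip(
                range(1, 15),
                [20, 58, 140, 213, 255, 275, 245, 197, 158, 93, 68, 28, 24, 11],
            )
        )
        counts[0] = 4
        counts[15] = 1796 - sum(counts.values())
        val = gwesp_from_esp(EspDistribution(counts), 0.45)
        assert val == pytest.approx(2766.98, abs=0.05)

    @given(st.integers(0, 2**40 - 1), st.integers(5, 12))
    @settings(max_examples=40, deadline=None)
    def test_two_code_paths_agree(self, bits, n):
        rng = np.random.default_rng(bits)
        g = random_graph(rng, n, 0.4)
        lam = float(rng.uniform(0.0, 2.0))
        a = gwesp_from_esp(esp_distribution(g), lam)
        b = gwesp_statistic(g, lam)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)

    @given(st.integers(0, 2**40 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_decay_and_bounded(self, bits):
        rng = np.random.default_rng(bits)
        g = random_graph(rng, 9, 0.45)
        esp = esp_distribution(g)
        lams = [0.0, 0.25, 0.5, 1.0, 2.0]
        vals = [gwesp_from_esp(esp, lam) for lam in lams]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        ep0 = esp.counts.get(0, 0)
        for lam, v in zip(lams, vals):
            assert v <= math.exp(lam) * (g.n_edges - ep0) + 1e-9


class TestMixingCounts:
    def test_three_nodes(self):
        g = make_graph([(0, 1), (0, 2)], 3)
        attrs = make_attrs("AAB")
        mix = mixing_counts(g, attrs)
        assert mix.counts == {("A", "A"): 1, ("A", "B"): 1, ("B", "B"): 0}

    def test_complete_graph_two_labels(self, k4):
        mix = mixing_counts(k4, make_attrs("AABB"))
        assert mix.counts == {("A", "A"): 1, ("A", "B"): 4, ("B", "B"): 1}

    @given(st.integers(0, 2**40 - 1), st.integers(4, 10))
    @settings(max_examples=40, deadline=None)
    def test_cells_sum_to_edge_count(self, bits, n):
        rng = np.random.default_rng(bits)
        g = random_graph(rng, n, 0.4)
        labels = [["A", "B", "C"][k % 3] for k in range(n)]
        assert mixing_counts(g, make_attrs(labels)).total == g.n_edges

    def test_missing_label_rejected(self, triangle):
        df = pd.DataFrame(
            {"rsn_label": ["A", None, "B"], "cortical_group": ["cortical"] * 3}
        )
        with pytest.raises(ValueError, match="no rsn_label"):
            NodeAttributeTable(df)


def brute_force_statistics(g, attrs, spec):
    """Naive per-term recomputation used as an independent oracle."""
    from itertools import combinations_with_replacement

    a = g.adjacency
    n = g.n_nodes
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if a[i, j]]
    vals = [float(len(edges))]
    labs = sorted(set(attrs.rsn_label))
    cells = list(combinations_with_replacement(labs, 2))
    lab = attrs.rsn_label
    for cell in cells:
        if cell == (labs[0], labs[0]):
            continue  # reference
        c = sum(1 for i, j in edges if tuple(sorted((lab[i], lab[j]))) == cell)
        vals.append(float(c))
    if spec.has_structural:
        for covname in ("struct_degree", "struct_efficiency", "struct_clustering"):
            x = attrs.covariate(covname)
            if spec.standardize_covariates:
                x = (x - x.mean()) / x.std()
            vals.append(float(sum(x[i] + x[j] for i, j in edges)))
        clus = attrs.latent_cluster
        vals.append(float(sum(1 for i, j in edges if clus[i] == clus[j])))
    if spec.has_gwesp:
        lam = spec.gwesp_decay
        tot = 0.0
        for i, j in edges:
            sp = sum(1 for k in range(n) if a[i, k] and a[j, k])
            tot += 1 - (1 - math.exp(-lam)) ** sp
        vals.append(math.exp(lam) * tot)
    return np.array(vals)


class TestComputeStatistics:
    def test_base_on_triangle(self, triangle):
        attrs = make_attrs("AAB")
        sv = compute_statistics(triangle, attrs, ModelSpec("base"))
        # the single-node label B admits no within-B dyads, so only the
        # A-B cell is estimable alongside the (dropped) A-A reference
        assert sv.term_names == ("edges", "mix.A.B")
        assert sv["edges"] == 3
        assert sv["mix.A.B"] == 2

    def test_nodecov_sum_raw(self, triangle):
        attrs = make_attrs("AAA")
        attrs.table["struct_degree"] = [1.0, 2.0, 3.0]
        attrs.table["struct_efficiency"] = [0.0, 0.0, 0.0]
        attrs.table["struct_clustering"] = [0.0, 0.0, 0.0]
        attrs.table["latent_cluster"] = [0, 0, 1]
        sv = compute_statistics(
            triangle, attrs, ModelSpec("structural", standardize_covariates=False)
        )
        # (1+2) + (1+3) + (2+3)
        assert sv["nodecov.struct_degree"] == pytest.approx(12.0)
        assert sv["nodematch.latent"] == 1.0

    def test_missing_covariates_raise(self, triangle):
        with pytest.raises(KeyError):
            compute_statistics(triangle, make_attrs("AAB"), ModelSpec("complete"))

    @pytest.mark.parametrize("spec_name", ["base", "structural", "gwesp", "complete"])
    def test_matches_brute_force_oracle(self, spec_name, rng):
        spec = ModelSpec(spec_name, gwesp_decay=0.45)
        for _ in range(5):
            g = random_graph(rng, 10, 0.35)
            labels = [["A", "B", "C"][k % 3] for k in range(10)]
            attrs = make_attrs(labels, rng=rng, structural=True)
            got = compute_statistics(g, attrs, spec)
            want = brute_force_statistics(g, attrs, spec)
            np.testing.assert_allclose(got.values, want, atol=1e-9)


class TestIO:
    def test_csv_roundtrip(self, tmp_path, rng):
        g = random_graph(rng, 12, 0.3)
        path = tmp_path / "adj.csv"
        write_adjacency(g, path)
        g2 = read_adjacency(path)
        np.testing.assert_array_equal(g.adjacency, g2.adjacency)

    def test_graphml_roundtrip(self, tmp_path, rng):
        g = random_graph(rng, 8, 0.4)
        path = tmp_path / "adj.graphml"
        write_adjacency(g, path)
        g2 = read_adjacency(path)
        assert g2.n_edges == g.n_edges

    def test_attribute_tsv_roundtrip(self, tmp_path, rng):
        attrs = make_attrs("AABBB", rng=rng, structural=True)
        path = tmp_path / "attrs.tsv"
        write_attributes(attrs, path)
        attrs2 = read_attributes(path)
        pd.testing.assert_frame_equal(attrs.table, attrs2.table)
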