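import math

import numpy as np
import pytest

from ergmix.ergm import (
    DegenerateFitError,
    DyadDesign,
    MCMCControl,
    change_statistics,
    chain_state_counts,
    enumerate_exact,
    mcmcmle_fit,
    mple_fit,
    sample_graphs,
    sample_statistics,
)
from ergmix.graph_core import compute_statistics, validate_graph
from ergmix.model import ModelSpec

from .conftest import make_attrs, random_graph


def brute_change(g, attrs, spec, i, j):
    ap = g.adjacency.copy()
    ap[i, j] = ap[j, i] = 1
    am = g.adjacency.copy()
    am[i, j] = am[j, i] = 0
    return (
        compute_statistics(validate_graph(ap), attrs, spec).values
        - compute_statistics(validate_graph(am), attrs, spec).values
    )


class TestChangeStatistics:
    def test_edges_term_always_one(self, triangle):
        attrs = make_attrs("AAB")
        d = change_statistics(triangle, attrs, ModelSpec("base"), (0, 2))
        assert d[0] == 1.0

    def test_nodecov_is_endpoint_sum(self, triangle):
        attrs = make_attrs("AAA")
        attrs.table["struct_degree"] = [1.0, 2.0, 3.0]
        attrs.table["struct_efficiency"] = [0.0] * 3
        attrs.table["struct_clustering"] = [0.0] * 3
        attrs.table["latent_cluster"] = [0, 1, 2]
        spec = ModelSpec("structural", standardize_covariates=False)
        d = change_statistics(triangle, attrs, spec, (0, 2))
        names = spec.term_names(attrs.labels)
        assert d[names.index("nodecov.struct_degree")] == pytest.approx(4.0)

    def test_self_loop_rejected(self, triangle):
        with pytest.raises(ValueError, match="self-loop"):
            change_statistics(triangle, make_attrs("AAB"), ModelSpec("base"), (1, 1))

    def test_gwesp_delta_matches_full_difference(self, rng):
        spec = ModelSpec("gwesp", 0.6)
        attrs = make_attrs("AABBC")
        for _ in range(10):
            g = random_graph(rng, 5, 0.5)
            design = DyadDesign(attrs, spec)
            for i in range(5):
                for j in range(i + 1, 5):
                    got = change_statistics(g, attrs, spec, (i, j), design=design)
                    want = brute_change(g, attrs, spec, i, j)
                    np.testing.assert_allclose(got, want, atol=1e-9)

    @pytest.mark.parametrize("spec_name", ["base", "structural", "gwesp", "complete"])
    def test_all_specs_match_oracle(self, spec_name, rng):
        spec = ModelSpec(spec_name, 0.45)
        n = 7
        labels = [["A", "B", "C"][k % 3] for k in range(n)]
        attrs = make_attrs(labels, rng=rng, structural=True)
        design = DyadDesign(attrs, spec)
        for _ in range(5):
            g = random_graph(rng, n, 0.4)
            for i in range(n):
                for j in range(i + 1, n):
                    got = change_statistics(g, attrs, spec, (i, j), design=design)
                    want = brute_change(g, attrs, spec, i, j)
                    np.testing.assert_allclose(got, want, atol=1e-9)


class TestMpleFit:
    def test_edges_only_closed_form(self, rng):
        # single label -> the base model reduces to an edges-only logit
        n = 15  # 105 dyads
        iu, ju = np.triu_indices(n, 1)
        a = np.zeros((n, n), dtype=int)
        pick = rng.choice(len(iu), 30, replace=False)
        a[iu[pick], ju[pick]] = 1
        g = validate_graph(a + a.T)
        fit = mple_fit(g, make_attrs("A" * n), ModelSpec("base"))
        d = 30 / 105
        assert fit.theta[0] == pytest.approx(math.log(d / (1 - d)), abs=1e-8)

    def test_two_label_mixing_closed_form(self, rng):
        n = 20
        labels = "A" * 10 + "B" * 10
        attrs = make_attrs(labels)
        g = random_graph(rng, n, 0.4)
        fit = mple_fit(g, attrs, ModelSpec("base"))
        # per-cell closed form: coefficient = cell logit - reference logit
        lab = np.array(list(labels))
        iu, ju = np.triu_indices(n, 1)
        y = g.adjacency[iu, ju]

        def cell_logit(a, b):
            pairs = [tuple(sorted(p)) for p in zip(lab[iu], lab[ju])]
            sel = np.array([p == (a, b) for p in pairs])
            d = y[sel].mean()
            return math.log(d / (1 - d))

        ref = cell_logit("A", "A")
        assert fit.theta[0] == pytest.approx(ref, abs=1e-6)
        assert fit.theta[fit.term("mix.A.B")] == pytest.approx(
            cell_logit("A", "B") - ref, abs=1e-6
        )
        assert fit.theta[fit.term("mix.B.B")] == pytest.approx(
            cell_logit("B", "B") - ref, abs=1e-6
        )

    def test_dyad_independent_recovery(self):
        # base model: dyads are independent Bernoulli with known logits,
        # so graphs can be sampled directly without MCMC
        n = 100
        labels = "A" * 50 + "B" * 50
        attrs = make_attrs(labels)
        spec = ModelSpec("base")
        design = DyadDesign(attrs, spec)
        theta = np.array([-1.5, 0.4, -0.3])
        probs = 1 / (1 + np.exp(-(design.static @ theta)))
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            yy = rng.random(design.n_dyads) < probs
            a = np.zeros((n, n), dtype=int)
            a[design.iu[yy], design.ju[yy]] = 1
            g = validate_graph(a + a.T)
            ests.append(mple_fit(g, attrs, spec).theta)
        ests = np.array(ests)
        mc_se = ests.std(axis=0, ddof=1) / math.sqrt(len(ests))
        np.testing.assert_array_less(np.abs(ests.mean(0) - theta), 2 * mc_se + 1e-9)

    def test_rank_deficiency_names_terms(self, rng):
        n = 12
        attrs = make_attrs("A" * n)
        attrs.table["struct_degree"] = 1.0  # constant -> z-scored to zeros
        attrs.table["struct_efficiency"] = 1.0
        attrs.table["struct_clustering"] = 1.0
        attrs.table["latent_cluster"] = 0
        g = random_graph(rng, n, 0.5)
        with pytest.raises(DegenerateFitError, match="rank"):
            mple_fit(g, attrs, ModelSpec("structural"))


class TestEnumerateExact:
    def test_uniform_at_zero_theta(self):
        attrs = make_attrs("AAA")
        ex = enumerate_exact(np.zeros(1), attrs, ModelSpec("base"))
        np.testing.assert_allclose(ex.probs, np.full(8, 1 / 8), atol=1e-12)
        assert ex.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_expected_edges_closed_form(self):
        attrs = make_attrs("AAA")
        theta = np.array([0.7])
        ex = enumerate_exact(theta, attrs, ModelSpec("base"))
        expect = 3 * math.exp(0.7) / (1 + math.exp(0.7))
        assert ex.expected_statistics()[0] == pytest.approx(expect, abs=1e-10)

    def test_gwesp_probability_ratio(self):
        # graphs with equal edges differ in probability by exp(theta_g * dG)
        attrs = make_attrs("AAAA")
        spec = ModelSpec("gwesp", 0.5)
        theta_g = 0.8
        theta = np.array([0.0, theta_g])
        ex = enumerate_exact(theta, attrs, spec)
        # triangle on nodes {0,1,2}: dyads (0,1),(0,2),(1,2)
        design = DyadDesign(attrs, spec)
        d = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(design.iu, design.ju))}
        tri = (1 << d[(0, 1)]) | (1 << d[(0, 2)]) | (1 << d[(1, 2)])
        path = (1 << d[(0, 1)]) | (1 << d[(0, 2)]) | (1 << d[(1, 3)])  # no triangle
        g_tri = ex.statistics[tri][1]
        g_path = ex.statistics[path][1]
        ratio = math.exp(ex.log_probs[tri] - ex.log_probs[path])
        assert ratio == pytest.approx(math.exp(theta_g * (g_tri - g_path)), rel=1e-10)

    def test_size_limit(self):
        attrs = make_attrs("AAAAAA")
        with pytest.raises(ValueError, match="n <= 5"):
            enumerate_exact(np.zeros(1), attrs, ModelSpec("base"))


class TestSampler:
    def test_zero_theta_mean_edges(self):
        attrs = make_attrs("AAAA")
        counts = chain_state_counts(
            np.zeros(1), attrs, ModelSpec("base"), n_steps=120_000, burn_in=2_000,
            seed=5,
        )
        codes = np.arange(64)
        mean_edges = (
            np.array([int(c).bit_count() for c in codes]) @ counts / counts.sum()
        )
        assert mean_edges == pytest.approx(3.0, abs=0.05)

    def test_strongly_negative_edges_theta_empties_graph(self):
        attrs = make_attrs("AAAA")
        graphs = sample_graphs(
            np.array([-10.0]), attrs, ModelSpec("base"), seed=3,
            burn_in=5_000, thinning=500, n_steps=10_000,
        )
        assert max(g.n_edges for g in graphs) <= 1

    def test_matches_exact_distribution_with_gwesp(self):
        attrs = make_attrs("AABB")
        spec = ModelSpec("gwesp", 0.5)
        theta = np.array([-0.4, 0.3, 0.2, 0.6])
        ex = enumerate_exact(theta, attrs, spec)
        counts = chain_state_counts(
            theta, attrs, spec, n_steps=300_000, burn_in=5_000, seed=9
        )
        emp = counts / counts.sum()
        tv = 0.5 * np.abs(emp - ex.probs).sum()
        assert tv < 0.02

    def test_reproducible_under_seed(self):
        attrs = make_attrs("AABB")
        kw = dict(burn_in=2_000, thinning=400, n_steps=6_000)
        a = sample_graphs(np.array([-0.5, 0.1, 0.2]), attrs, ModelSpec("base"),
                          seed=77, **kw)
        b = sample_graphs(np.array([-0.5, 0.1, 0.2]), attrs, ModelSpec("base"),
                          seed=77, **kw)
        for ga, gb in zip(a, b):
            np.testing.assert_array_equal(ga.adjacency, gb.adjacency)

    def test_requires_steps_beyond_burnin(self):
        attrs = make_attrs("AA")
        with pytest.raises(ValueError):
            sample_graphs(np.zeros(1), attrs, ModelSpec("base"),
                          n_steps=10, burn_in=20)


class TestMcmcMle:
    def test_base_spec_reduces_to_mple(self, rng):
        n = 30
        labels = "A" * 15 + "B" * 15
        attrs = make_attrs(labels)
        g = random_graph(rng, n, 0.3)
        a = mple_fit(g, attrs, ModelSpec("base"))
        b = mcmcmle_fit(g, attrs, ModelSpec("base"), seed=0)
        np.testing.assert_allclose(a.theta, b.theta, atol=1e-6)
        assert b.method == "MCMC-MLE"
        assert "dyad-independent" in b.notes

    def test_gwesp_recovery_small(self):
        # single replicate sanity run; the full recovery experiment lives
        # in the acceptance suite
        n = 40
        attrs = make_attrs("A" * 20 + "B" * 20)
        spec = ModelSpec("gwesp", 0.5)
        design = DyadDesign(attrs, spec)
        theta_true = np.array([-2.2, 0.1, 0.3, 0.5])
        from ergmix.ergm import _init_masks, _run_chain
        from ergmix.graph_core import bitmasks_to_adjacency

        r = np.random.default_rng(4)
        masks = _init_masks(design, r, 0.15)
        _run_chain(design, theta_true, masks, 250_000, r)
        g = validate_graph(bitmasks_to_adjacency(masks, n))
        fit = mcmcmle_fit(g, attrs, spec, seed=21)
        assert fit.converged
        np.testing.assert_array_less(np.abs(fit.theta - theta_true), 0.6)

    def test_degenerate_near_complete_graph(self):
        # near-complete observed graph with a strong positive GWESP pull:
        # the chain collapses to the complete graph and the fit reports it
        n = 12
        a = 1 - np.eye(n, dtype=int)
        a[0, 1] = a[1, 0] = 0  # one missing edge
        g = validate_graph(a)
        attrs = make_attrs("A" * n)
        fit = mcmcmle_fit(
            g, attrs, ModelSpec("gwesp", 0.5), seed=1,
            control=MCMCControl(max_iter=3, n_samples=40),
        )
        if not fit.converged:
            assert np.isnan(fit.std_err).all()  # inference withheld
        else:
            # if it converged the estimate must reproduce the near-complete density
            assert fit.theta is not None

    def test_incremental_stats_match_recompute(self, rng):
        # chain-final state statistics equal a from-scratch recomputation
        attrs = make_attrs("AABBC", rng=rng, structural=True)
        spec = ModelSpec("complete", 0.5)
        design = DyadDesign(attrs, spec)
        sims, masks = sample_statistics(
            np.zeros(design.p), design, 3, burn_in=500, thinning=200, seed=0
        )
        g = validate_graph(
            __import__("ergmix.graph_core", fromlist=["bitmasks_to_adjacency"])
            .bitmasks_to_adjacency(masks, 5)
        )
        np.testing.assert_allclose(
            sims[-1], compute_statistics(g, attrs, spec).values, atol=1e-9
        )
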