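import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exoncnv import (
    Gene,
    PriorTable,
    TargetSet,
    call_events,
    compute_odf,
    likelihood,
    neighbor_rescue,
    poisson_zscores,
    posterior,
)
from exoncnv.calling import merge_callsets


class TestPoissonZscores:
    def test_arithmetic(self):
        z = poisson_zscores(np.array([[400.0, 380.0]]), np.array([[400.0, 400.0]]))
        np.testing.assert_allclose(z, [[0.0, -1.0]])

    def test_unit_spread_under_poisson(self):
        rng = np.random.default_rng(0)
        obs = rng.poisson(400.0, 10_000).astype(float)
        z = poisson_zscores(obs, np.full(10_000, 400.0))
        assert np.std(z) == pytest.approx(1.0, abs=0.05)

    def test_zero_expectation_rejected(self):
        with pytest.raises(ValueError):
            poisson_zscores(np.array([1.0]), np.array([0.0]))


class TestComputeOdf:
    def test_poisson_baseline_floors_at_one(self):
        rng = np.random.default_rng(1)
        z = rng.normal(0.0, 1.0, (200, 50))
        odf = compute_odf(z)
        assert np.median(odf.gss_odf) == pytest.approx(1.0, abs=0.05)

    def test_uniform_eightfold_inflation_maps_to_eight(self):
        rng = np.random.default_rng(2)
        z = rng.normal(0.0, 8.0, (400, 100))
        odf = compute_odf(z)
        assert np.median(odf.gss_odf) == pytest.approx(8.0, rel=0.05)

    def test_product_clamped_to_twenty(self):
        rng = np.random.default_rng(3)
        z = rng.normal(0.0, 25.0, (200, 50))
        odf = compute_odf(z)
        assert odf.gss_odf.max() == 20.0

    def test_constant_z_floors_at_odf_min(self):
        odf = compute_odf(np.ones((5, 5)))
        assert (odf.gss_odf == 1.0).all()

    def test_outlying_events_do_not_inflate_dispersion(self):
        # a handful of strong deletion signals must not mask themselves by
        # inflating the gene's estimated spread
        rng = np.random.default_rng(4)
        z = rng.normal(0.0, 2.0, (100, 50))
        z_spiked = z.copy()
        z_spiked[0, :3] = -25.0
        clean = compute_odf(z).gene_odf[0]
        spiked = compute_odf(z_spiked).gene_odf[0]
        assert spiked == pytest.approx(clean, rel=0.1)


class TestLikelihood:
    def test_peak_density_of_normal_model(self):
        rd_exp, odf = 400.0, 2.0
        val = likelihood(np.array([400.0]), np.array([rd_exp]),
                         np.array([odf]), 2)
        assert val[0] == pytest.approx(1.0 / (odf * np.sqrt(2 * np.pi * rd_exp)))

    def test_hom_deletion_mean_is_residual_fraction(self):
        from exoncnv.calling import cn_means

        mu = cn_means(np.array([1000.0]))
        assert mu[0, 0] == 10.0
        assert mu[0, 2] == 1000.0
        assert mu[0, 5] == 2500.0

    def test_cn1_cn2_likelihood_ratio_closed_form(self):
        # at RD = RD_exp/2 the ratio is sqrt(2) * exp(QI^2 / 8)
        rd_exp, odf = 400.0, 2.0
        qi = np.sqrt(rd_exp) / odf
        obs = np.array([rd_exp / 2.0])
        l1 = likelihood(obs, np.array([rd_exp]), np.array([odf]), 1)
        l2 = likelihood(obs, np.array([rd_exp]), np.array([odf]), 2)
        assert l1[0] / l2[0] == pytest.approx(
            np.sqrt(2.0) * np.exp(qi**2 / 8.0), rel=1e-9
        )

    def test_nbinom_family_agrees_with_normal_at_high_depth(self):
        from exoncnv.calling import log_likelihood

        ll_n = log_likelihood(2000.0, 2000.0, 3.0, 2, family="normal")
        ll_nb = log_likelihood(2000.0, 2000.0, 3.0, 2, family="nbinom")
        assert ll_n == pytest.approx(ll_nb, abs=0.05)


class TestPosterior:
    def test_diploid_depth_gives_confident_cn2(self, priors):
        post = posterior(400.0, 400.0, 2.0, priors)
        assert post.argmax() == 2
        assert post[2] > 0.999

    def test_half_depth_gives_confident_het_deletion(self, priors):
        # the observed/expected pair printed for the BCL2L15 call
        post = posterior(533.0, 1158.0, 2.0, priors)
        assert post.argmax() == 1
        assert post[1] > 0.99

    def test_zero_depth_gives_hom_deletion(self, priors):
        post = posterior(0.0, 1000.0, 2.0, priors)
        assert post.argmax() == 0

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        rd_exp=st.floats(20.0, 50_000.0),
        ratio=st.floats(0.0, 3.0),
        odf=st.floats(1.0, 20.0),
    )
    def test_posterior_sums_to_one_everywhere(self, rd_exp, ratio, odf):
        post = posterior(ratio * rd_exp, rd_exp, odf)
        assert post.sum() == pytest.approx(1.0, abs=1e-9)
        assert (post >= 0).all()

    def test_cn1_posterior_unimodal_with_peak_near_half_depth(self, priors):
        rd_exp, odf = 2000.0, 2.0
        grid = np.linspace(0, 1.2 * rd_exp, 400)
        p1 = posterior(grid, np.full_like(grid, rd_exp),
                       np.full_like(grid, odf), priors)[:, 1]
        half_idx = np.argmin(np.abs(grid - rd_exp / 2))
        assert p1[half_idx] == pytest.approx(p1.max(), abs=1e-9)
        # unimodal: every superlevel set is a contiguous RD interval
        for level in (0.1, 0.5, 0.9):
            above = np.flatnonzero(p1 >= level)
            assert above.size > 0
            assert np.array_equal(above, np.arange(above[0], above[-1] + 1))

    def test_no_underflow_at_extreme_depth(self, priors):
        post = posterior(50_000.0, 100.0, 1.0, priors)
        assert np.isfinite(post).all()
        assert post.sum() == pytest.approx(1.0, abs=1e-9)


class TestCallEvents:
    def _run(self, p1, h):
        post = np.zeros((1, 1, 10))
        post[0, 0, 1] = p1
        post[0, 0, 2] = 1 - p1
        return call_events(
            post, np.array([[100.0]]), np.array([[200.0]]), np.array([[2.0]]),
            ["G"], ["S"], h_call=h,
        )

    def test_threshold_inclusive(self):
        assert len(self._run(0.66, 0.65)) == 1
        assert len(self._run(0.65, 0.65)) == 1
        assert len(self._run(0.64, 0.65)) == 0

    def test_amplification_called(self):
        post = np.zeros((1, 1, 10))
        post[0, 0, 3] = 0.99
        post[0, 0, 2] = 0.01
        calls = call_events(
            post, np.array([[300.0]]), np.array([[200.0]]), np.array([[2.0]]),
            ["G"], ["S"], h_call=0.65,
        )
        assert calls[0].called_cn == 3


class TestNeighborRescue:
    def _post(self, p_del_by_gene):
        post = np.zeros((len(p_del_by_gene), 1, 10))
        for i, p in enumerate(p_del_by_gene):
            post[i, 0, 1] = p
            post[i, 0, 2] = 1 - p
        return post

    def _rescue(self, targets, genes, p_del, max_dist=3_000_000):
        post = self._post(p_del)
        zeros = np.zeros((len(genes), 1))
        return neighbor_rescue(
            post, genes, ["S"], targets, zeros, zeros + 100.0, zeros + 2.0,
            h_neighbor=0.1, neighbor_max_distance=max_dist,
        )

    def test_adjacent_pair_rescued(self, toy_targets):
        # GENE_A and GENE_B are 1 Mb apart: both weak candidates -> rescued
        calls = self._rescue(toy_targets, ["GENE_A", "GENE_B"], [0.3, 0.3])
        assert {c.gene for c in calls} == {"GENE_A", "GENE_B"}
        assert all(c.neighbor_supported for c in calls)

    def test_distance_cap_blocks_rescue(self, toy_targets):
        calls = self._rescue(toy_targets, ["GENE_A", "GENE_B"], [0.3, 0.3],
                             max_dist=500_000)
        assert calls == []

    def test_intervening_quiet_gene_breaks_immediacy(self, toy_targets):
        # A and C are candidates but B sits between them below threshold
        calls = self._rescue(
            toy_targets, ["GENE_A", "GENE_B", "GENE_C"], [0.3, 0.01, 0.3]
        )
        assert calls == []

    def test_different_chromosome_not_neighbors(self, toy_targets):
        calls = self._rescue(toy_targets, ["GENE_C", "GENE_D"], [0.3, 0.3])
        assert calls == []

    def test_union_keeps_standalone_provenance(self, toy_targets):
        rescued = self._rescue(toy_targets, ["GENE_A", "GENE_B"], [0.3, 0.3])
        post = self._post([0.95, 0.3])
        zeros = np.zeros((2, 1))
        primary = call_events(
            post, zeros, zeros + 100.0, zeros + 2.0, ["GENE_A", "GENE_B"],
            ["S"], 0.65, toy_targets,
        )
        merged = merge_callsets(primary, rescued)
        by_gene = {c.gene: c for c in merged}
        assert not by_gene["GENE_A"].neighbor_supported  # standalone wins
        assert by_gene["GENE_B"].neighbor_supported
        # every standalone call is present in the union
        assert {(c.sample, c.gene) for c in primary} <= {
            (c.sample, c.gene) for c in merged
        }
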