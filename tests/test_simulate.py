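"""Synthetic generator: inverse construction, reproducibility, recovery."""

import numpy as np
import pytest

import mcdmkit as mk


def wv(*weights, gid="g"):
    return mk.WeightVector(gid, tuple(weights))


class TestConsistentMatrixFromWeights:
    def test_uniform_weights_give_indifference(self):
        m = mk.consistent_matrix_from_weights(wv(0.25, 0.25, 0.25, 0.25))
        assert np.allclose(m.values, 0.5)

    def test_two_attribute_inverse_of_weight_rule(self):
        m = mk.consistent_matrix_from_weights(wv(0.625, 0.375))
        assert m.values[0, 1] == pytest.approx(0.75, abs=1e-12)

    def test_matrix_is_consistent_and_round_trips(self):
        w = wv(0.4667, 0.3333, 0.2000)
        m = mk.consistent_matrix_from_weights(w)
        m.check()
        back = mk.weights_from_matrix(m, group_id="g")
        assert np.abs(back.as_array() - w.as_array()).max() < 1e-12

    def test_spread_violation_raises(self):
        with pytest.raises(ValueError, match="compress"):
            mk.consistent_matrix_from_weights(wv(0.7, 0.2, 0.1))


class TestChainFromWeights:
    def test_uniform_gives_chain_of_halves(self):
        ch = mk.chain_from_weights(wv(0.25, 0.25, 0.25, 0.25))
        assert ch.values == pytest.approx((0.5, 0.5, 0.5))

    def test_known_chain_recovered(self):
        # exact inverse of the (0.7, 0.7) completion example: row sums
        # 2.1, 1.5, 0.9 over 4.5
        ch = mk.chain_from_weights(wv(2.1 / 4.5, 1.5 / 4.5, 0.9 / 4.5))
        assert ch.values == pytest.approx((0.7, 0.7), abs=1e-12)

    def test_single_attribute_gives_empty_chain(self):
        assert mk.chain_from_weights(wv(1.0)).values == ()

    def test_round_trip_recovers_weights_exactly(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            k = rng.integers(2, 7)
            w = rng.dirichlet(np.ones(k) * 8)  # concentrated => feasible spread
            w = mk.compress_weights(wv(*w))
            back = mk.chain_weights(mk.chain_from_weights(w))
            assert np.abs(back.as_array() - w.as_array()).max() < 1e-12


class TestCompressWeights:
    def test_feasible_vector_unchanged(self):
        w = wv(0.4, 0.35, 0.25)
        assert mk.compress_weights(w) is w

    def test_compression_reaches_target_and_keeps_ranking(self):
        w = wv(0.0935, 0.2021, 0.3253, 0.3791)  # spread 0.5712, infeasible
        c = mk.compress_weights(w)
        arr = c.as_array()
        assert len(arr) * (arr.max() - arr.min()) / 2 <= 0.499 + 1e-12
        assert mk.rank_weights(c.weights) == mk.rank_weights(w.weights)
        assert arr.sum() == pytest.approx(1.0, abs=1e-12)


class TestGeneratePanel:
    def test_same_seed_gives_byte_identical_csvs(self, tmp_path):
        cfg = mk.hhnjs_generator_config(seed=42, n=5)
        a, b = tmp_path / "a", tmp_path / "b"
        mk.simulate_to_dir(cfg, a)
        mk.simulate_to_dir(mk.hhnjs_generator_config(seed=42, n=5), b)
        for name in ("judgments.csv", "ratings.csv", "truth.json"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        cfg1 = mk.hhnjs_generator_config(seed=1, n=3)
        cfg2 = mk.hhnjs_generator_config(seed=2, n=3)
        p1, p2 = mk.generate_panel(cfg1), mk.generate_panel(cfg2)
        assert p1.judgments != p2.judgments

    def test_generated_panel_passes_validation_and_shapes(self):
        cfg = mk.hhnjs_generator_config(seed=0, n=4)
        panel = mk.generate_panel(cfg)  # validates internally
        assert panel.n == 4
        k_per_group = {g: len(m) for g, m in cfg.instrument.groups().items()}
        expected_judgments = 4 * sum(k - 1 for k in k_per_group.values())
        assert len(panel.judgments) == expected_judgments
        assert len(panel.ratings) == 4 * 30

    def test_noiseless_ratings_round_latent_means(self):
        cfg = mk.hhnjs_generator_config(seed=0, n=2, judgment_noise=0.0, rating_noise=0.0)
        cfg.true_performance = {c: 3.5 for c in cfg.instrument.criterion_ids}
        panel = mk.generate_panel(cfg)
        assert {r.rating for r in panel.ratings} == {4}  # half-up at the boundary

    def test_infeasible_truth_rejected_before_generation(self, toy_instrument):
        cfg = mk.GeneratorConfig(
            instrument=toy_instrument,
            true_weights={
                "DIMS": wv(0.5, 0.5, gid="DIMS"),
                "D1": wv(0.5, 0.5, gid="D1"),
                "D2": wv(0.7, 0.2, 0.1, gid="D2"),  # spread 0.9
            },
            true_performance={c: 3.0 for c in toy_instrument.criterion_ids},
            n=2,
            seed=0,
        )
        with pytest.raises(ValueError, match="spread.*compress"):
            mk.generate_panel(cfg)

    def test_rank_recovery_degrades_with_noise(self):
        """Kendall tau between true and recovered global rankings is 1 when
        noiseless and stays high but (weakly) lower under noise."""
        from scipy.stats import kendalltau

        taus = {}
        for sigma in (0.0, 0.05):
            vals = []
            for seed in range(3):
                cfg = mk.hhnjs_generator_config(
                    seed=seed, judgment_noise=sigma, rating_noise=0.5
                )
                panel = mk.generate_panel(cfg)
                res = mk.run_pipeline(cfg.instrument, panel)
                truth = np.concatenate(
                    [
                        np.asarray(cfg.true_weights[d.id].weights)
                        * cfg.true_weights[mk.DIMENSION_GROUP].weights[i]
                        for i, d in enumerate(cfg.instrument.dimensions)
                    ]
                )
                rec = res.weight_table.criteria["global_weight"].to_numpy()
                vals.append(kendalltau(truth, rec).statistic)
            taus[sigma] = np.mean(vals)
        assert taus[0.0] == pytest.approx(1.0, abs=1e-12)
        assert taus[0.05] <= taus[0.0]
        assert taus[0.05] > 0.8  # recovery remains strong at study-like noise
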