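import math

import numpy as np
import pytest

from memswitch.distribution_fit import (
    CuHistogram,
    bootstrap_ci,
    cu_histogram,
    grid_search,
    jaccard_score,
    make_log_edges,
)


def _uniform_hist(edges, lo, hi):
    """Unit-area uniform density on [lo, hi] of the log axis."""
    edges = np.asarray(edges, float)
    w = edges[1] - edges[0]
    dens = np.zeros(edges.size - 1)
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        overlap = max(0.0, min(b, hi) - max(a, lo))
        dens[i] = overlap / (w * (hi - lo))
    return CuHistogram(edges, dens, 0.0)


class TestCuHistogram:
    def test_all_zero_activity_underflows(self):
        edges = np.linspace(math.log10(0.5), 2, 31)
        h = cu_histogram(np.zeros(100), edges)
        assert h.underflow_mass == 1.0
        assert np.all(h.densities == 0.0)

    def test_single_bin_concentration(self):
        edges = np.linspace(0, 3, 4)
        h = cu_histogram(np.full(50, 15.0), edges)  # log10 = 1.18 -> bin 1
        assert h.densities[1] > 0
        assert h.densities[0] == h.densities[2] == 0
        assert h.underflow_mass == 0.0

    def test_mass_conservation_with_lognormal_draws(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(1.0, 1.0, 1000)
        edges = make_log_edges(vals)
        h = cu_histogram(vals, edges)
        total = h.densities.sum() * h.bin_width + h.underflow_mass
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_non_uniform_edges_rejected(self):
        with pytest.raises(ValueError):
            cu_histogram([1.0, 2.0], np.array([0.0, 1.0, 3.0]))


class TestJaccardScore:
    edges = np.linspace(0.0, 2.0, 21)

    def test_identical_histograms_score_one(self):
        h = _uniform_hist(self.edges, 0.2, 1.2)
        assert jaccard_score([h, h], [h, h]) == pytest.approx(1.0)

    def test_disjoint_supports_score_zero(self):
        a = _uniform_hist(self.edges, 0.0, 0.5)
        b = _uniform_hist(self.edges, 1.0, 1.5)
        assert jaccard_score([a], [b]) == pytest.approx(0.0)

    def test_half_overlap_scores_one_third(self):
        a = _uniform_hist(self.edges, 0.0, 1.0)
        b = _uniform_hist(self.edges, 0.5, 1.5)
        assert jaccard_score([a], [b]) == pytest.approx(1 / 3, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = cu_histogram(rng.lognormal(0.5, 0.6, 500), self.edges)
        b = cu_histogram(rng.lognormal(0.9, 0.4, 500), self.edges)
        assert jaccard_score([a], [b]) == pytest.approx(
            jaccard_score([b], [a]), abs=1e-15
        )

    def test_translation_monotonically_decreases_overlap(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0.0, 0.3, 4000)
        edges = np.linspace(-1.5, 3.5, 51)
        ref = cu_histogram(10.0 ** base, edges)
        scores = [
            jaccard_score([ref], [cu_histogram(10.0 ** (base + shift), edges)])
            for shift in (0.0, 0.3, 0.6, 0.9)
        ]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_mismatched_edges_rejected(self):
        a = _uniform_hist(self.edges, 0.0, 1.0)
        b = _uniform_hist(np.linspace(0.0, 2.0, 11), 0.0, 1.0)
        with pytest.raises(ValueError):
            jaccard_score([a], [b])

    def test_underflow_counts_as_pseudo_bin(self):
        h_full = CuHistogram(self.edges, np.zeros(20), 1.0)
        assert jaccard_score([h_full], [h_full]) == pytest.approx(1.0)


class _GaussianGenerator:
    """Tiny stand-in 'simulator': per-cell C.U. ~ 10^N(log10(mu), 0.2)."""

    def __init__(self, n_cells=2000):
        self.n_cells = n_cells

    def __call__(self, params, seed):
        rng = np.random.default_rng(seed)
        mu = params["mu"]
        return {
            "t": 10.0 ** rng.normal(math.log10(mu), 0.2, self.n_cells)
        }


class TestGridSearch:
    def test_self_consistency_truth_attains_maximum(self):
        gen = _GaussianGenerator()
        obs = gen({"mu": 1.0}, seed=999)
        # geometric grid (0.1, 1, 10) contains the truth exactly
        res = grid_search(obs, gen, {"mu": (0.1, 10.0)}, seed=5,
                          n_coarse=3, n_fine=3, n_refine=1)
        assert res.best_params["mu"] == pytest.approx(1.0, rel=0.35)

    def test_reproducible_given_seed(self):
        gen = _GaussianGenerator(500)
        obs = gen({"mu": 2.0}, seed=42)
        r1 = grid_search(obs, gen, {"mu": (0.2, 20.0)}, seed=9,
                         n_coarse=4, n_fine=3, n_refine=1)
        r2 = grid_search(obs, gen, {"mu": (0.2, 20.0)}, seed=9,
                         n_coarse=4, n_fine=3, n_refine=1)
        assert r1.best_params == r2.best_params
        assert r1.evaluations["jaccard"].equals(r2.evaluations["jaccard"])

    def test_constraint_vetoes_and_empty_grid_raises(self):
        gen = _GaussianGenerator(200)
        obs = gen({"mu": 1.0}, seed=1)
        res = grid_search(obs, gen, {"mu": (0.1, 10.0)}, seed=2,
                          n_coarse=3, n_fine=3, n_refine=0,
                          constraint=lambda p: p["mu"] < 5.0)
        assert res.best_params["mu"] < 5.0
        with pytest.raises(RuntimeError):
            grid_search(obs, gen, {"mu": (0.1, 10.0)}, seed=2,
                        n_coarse=3, n_fine=3, n_refine=0,
                        constraint=lambda p: False)

    def test_invalid_range_rejected(self):
        gen = _GaussianGenerator(100)
        obs = gen({"mu": 1.0}, seed=1)
        with pytest.raises(ValueError):
            grid_search(obs, gen, {"mu": (0.0, 1.0)}, seed=0)


class TestBootstrapCi:
    def test_zero_variance_data_collapse_interval(self):
        obs = {"t": np.full(50, 3.0)}

        def search_fn(resampled, seed):
            return {"theta": float(np.mean(resampled["t"]))}

        # constant data are degenerate under resampling by construction,
        # so use nearly-constant data instead
        obs = {"t": np.concatenate([np.full(49, 3.0), [3.0 + 1e-12]])}
        out = bootstrap_ci(obs, search_fn, n_boot=10, seed=1)
        assert out["theta"]["sd"] == pytest.approx(0.0, abs=1e-9)
        assert out["theta"]["lo"] == pytest.approx(out["theta"]["hi"],
                                                   abs=1e-9)

    def test_interval_covers_truth_for_mean_estimator(self):
        rng = np.random.default_rng(7)
        obs = {"t": rng.normal(5.0, 1.0, 200)}

        def search_fn(resampled, seed):
            return {"theta": float(np.mean(resampled["t"]))}

        out = bootstrap_ci(obs, search_fn, n_boot=50, seed=3)
        assert out["theta"]["lo"] <= 5.0 <= out["theta"]["hi"]
        # bootstrap SD approximates the SE of the mean
        assert out["theta"]["sd"] == pytest.approx(1.0 / math.sqrt(200),
                                                   rel=0.5)

    def test_requires_two_resamples(self):
        with pytest.raises(ValueError):
            bootstrap_ci({"t": np.ones(5)}, lambda o, s: {}, n_boot=1, seed=0)
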