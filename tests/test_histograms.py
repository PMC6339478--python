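import numpy as np
import pytest
from scipy import stats

from natlab.histograms import (
    GaussianComponentMixture,
    HistogramSpec,
    InsufficientDataError,
    build_histogram,
    decompose,
)
from natlab.histograms import test_normality as normality_screen


class TestBuildHistogram:
    def test_counts_values_into_fixed_bins(self):
        hist = build_histogram(np.array([3.0, 3.0, 7.0]), "noc", [0, 5, 10])
        assert list(hist.counts) == [2, 1]
        assert hist.total == 3

    def test_diameters_are_binned_on_log_scale(self):
        td = np.exp(7.0)  # ~1096.6 µm lands in the ln-bin [6.95, 7.05)
        edges = np.arange(6.05, 8.06, 0.1)
        hist = build_histogram(np.array([td]), "td", edges)
        centers = hist.centers
        assert centers[hist.counts.argmax()] == pytest.approx(7.0, abs=0.05)

    def test_value_outside_edges_raises(self):
        with pytest.raises(ValueError, match="outside"):
            build_histogram(np.array([12.0]), "noc", [0, 5, 10])

    def test_total_is_conserved(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(40, 6, size=137)
        edges = np.arange(0, 105, 5)
        assert build_histogram(vals, "noc", edges).total == 137


class TestNormalityScreen:
    def test_normal_shaped_counts_pass(self):
        edges = np.arange(0, 105, 5)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = np.round(200 * 5 * stats.norm.pdf(centers, 50, 10)).astype(int)
        stat, p = normality_screen(HistogramSpec(edges, counts, "noc"))
        assert p > 0.9

    def test_bimodal_counts_reject(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(30, 3, 150), rng.normal(60, 3, 150)])
        edges = np.arange(0, 105, 5)
        _, p = normality_screen(build_histogram(vals, "noc", edges))
        assert p < 1e-6

    def test_type_one_error_rate_is_calibrated(self):
        """On single-normal draws (n=200) the 5% screen rejects rarely."""
        edges = np.arange(0, 105, 5)
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals = np.clip(rng.normal(45, 8, size=200), 1, 99)
            _, p = normality_screen(build_histogram(vals, "noc", edges))
            rejections += p < 0.05
        assert rejections <= 10

    def test_too_few_bins_is_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            normality_screen(HistogramSpec([0, 5, 10, 15], [0, 8, 0], "noc"))


class TestDecomposition:
    def test_two_planted_normals_recovered(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(30, 4, 120), rng.normal(55, 6, 80)])
        edges = np.arange(0, 105, 5)
        res = decompose(build_histogram(vals, "noc", edges), k_max=3, rng_seed=0)
        assert len(res.components) == 2
        means = sorted(c.mean for c in res.components)
        assert means[0] == pytest.approx(30, abs=1.5)
        assert means[1] == pytest.approx(55, abs=1.5)

    def test_all_mass_in_one_bin_gives_single_component_at_midpoint(self):
        edges = np.arange(0, 30, 5)
        counts = np.array([0, 0, 25, 0, 0])
        res = decompose(HistogramSpec(edges, counts, "noc"), k_max=3, rng_seed=0)
        assert len(res.components) == 1
        assert res.components[0].mean == pytest.approx(12.5, abs=1.0)

    def test_component_weights_sum_to_sample_size(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(30, 4, 120), rng.normal(55, 6, 80)])
        edges = np.arange(0, 105, 5)
        res = decompose(build_histogram(vals, "noc", edges), rng_seed=0)
        total = sum(c.weight for c in res.components)
        assert total == pytest.approx(200, rel=0.15)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(30, 4, 100), rng.normal(55, 6, 100)])
        hist = build_histogram(vals, "noc", np.arange(0, 105, 5))
        a = decompose(hist, rng_seed=11)
        b = decompose(hist, rng_seed=11)
        assert [(c.density, c.mean, c.sd) for c in a.components] == [
            (c.density, c.mean, c.sd) for c in b.components
        ]

    def test_single_normal_data_selects_one_component(self):
        """The 20%-improvement rule keeps k=1 on unimodal data."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = rng.normal(45, 7, size=150)
            hist = build_histogram(vals, "noc", np.arange(0, 105, 5))
            res = decompose(hist, k_max=3, rng_seed=seed)
            hits += len(res.components) == 1
        assert hits >= 18

    def test_components_sorted_by_mean_descending(self):
        rng = np.random.default_rng(9)
        vals = np.concatenate([rng.normal(30, 4, 100), rng.normal(55, 5, 100)])
        res = decompose(build_histogram(vals, "noc", np.arange(0, 105, 5)), rng_seed=0)
        means = [c.mean for c in res.components]
        assert means == sorted(means, reverse=True)


class TestEstimator:
    def test_sklearn_interface_and_ln_back_transform(self):
        rng = np.random.default_rng(2)
        td = np.exp(np.concatenate([rng.normal(7.0, 0.1, 120), rng.normal(7.9, 0.15, 80)]))
        est = GaussianComponentMixture(bin_width=0.1, log_transform=True, random_state=0)
        est.fit(td)
        assert est.n_components_ == 2
        means = sorted(c.mean for c in est.components_)  # back in µm
        assert means[0] == pytest.approx(np.exp(7.0), rel=0.05)
        assert means[1] == pytest.approx(np.exp(7.9), rel=0.05)
        # delta-method sd on the µm scale
        big = max(est.components_, key=lambda c: c.mean)
        assert big.sd == pytest.approx(0.15 * big.mean, rel=0.4)

    def test_get_params_roundtrip(self):
        est = GaussianComponentMixture(k_max=2, bin_width=3.0)
        assert GaussianComponentMixture(**est.get_params()).get_params() == est.get_params()
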