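import numpy as np
import pytest

from exocnv.depthio import CaptureRegion, Sample
from exocnv.genotype import (
    CopyNumberModel,
    GenotypeCalls,
    WindowDepthMatrix,
    adjust_window_matrix,
    build_window_matrix,
    call_genotypes,
    concordance,
    fit_population_hmm,
    viterbi_path,
)
from exocnv.pca import GlobalPCSet


def make_windows(values, window_size=100):
    values = np.asarray(values, dtype=float)
    region = CaptureRegion("chr1", 0, values.shape[0] * window_size, "L")
    starts = window_size * np.arange(values.shape[0])
    return WindowDepthMatrix(region, values, starts, window_size)


def uniform_mixture_em_oracle(x, means, variances, n_iter):
    """Independent single-window oracle: Gaussian mixture EM with fixed
    uniform weights, free means/variances — the model the one-window HMM
    collapses to."""
    means, variances = np.array(means, float), np.array(variances, float)
    for _ in range(n_iter):
        logp = -0.5 * (np.log(2 * np.pi * variances)[None, :]
                       + (x[:, None] - means[None, :]) ** 2 / variances[None, :])
        logp -= logp.max(axis=1, keepdims=True)
        post = np.exp(logp)
        post /= post.sum(axis=1, keepdims=True)
        w = post.sum(axis=0)
        for s in range(means.size):
            if w[s] < 1e-9:
                continue
            means[s] = post[:, s] @ x / w[s]
            variances[s] = max(post[:, s] @ (x - means[s]) ** 2 / w[s], 1e-6)
    logp = -0.5 * (np.log(2 * np.pi * variances)[None, :]
                   + (x[:, None] - means[None, :]) ** 2 / variances[None, :])
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=1, keepdims=True)
    return means, variances, post


class TestBuildWindowMatrix:
    def _samples(self, n, mean=15.0):
        return [Sample(f"s{i}", 0, mean_depth=mean) for i in range(n)]

    def test_window_anchoring_drops_partial_tail(self):
        region = CaptureRegion("chr1", 1000, 1350, "L")
        depth = np.ones((350, 2)) * 15
        wm = build_window_matrix(depth, region, self._samples(2))
        assert wm.values.shape == (3, 2)
        assert list(wm.window_starts) == [1000, 1100, 1200]

    def test_depth_at_sample_mean_gives_one(self):
        region = CaptureRegion("chr1", 0, 200, "L")
        wm = build_window_matrix(np.full((200, 3), 15.0), region, self._samples(3))
        assert wm.values == pytest.approx(np.ones((2, 3)))

    def test_zero_depth_gives_zero(self):
        region = CaptureRegion("chr1", 0, 100, "L")
        wm = build_window_matrix(np.zeros((100, 1)), region, self._samples(1))
        assert wm.values == pytest.approx(np.zeros((1, 1)))

    def test_interval_shorter_than_window_errors(self):
        region = CaptureRegion("chr1", 0, 80, "L")
        with pytest.raises(ValueError, match="shorter than one"):
            build_window_matrix(np.zeros((80, 1)), region, self._samples(1))


class TestAdjustWindowMatrix:
    @pytest.fixture
    def gpcs(self, rng):
        basis, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        return GlobalPCSet(basis.T[:4], np.linspace(4, 1, 4))

    def test_h_zero_identity(self, gpcs, rng):
        wm = make_windows(rng.normal(size=(5, 8)))
        out = adjust_window_matrix(wm, gpcs, 0)
        assert out.values == pytest.approx(wm.values)

    def test_row_equal_to_component_vanishes(self, gpcs):
        wm = make_windows(np.tile(gpcs.components[0], (3, 1)))
        out = adjust_window_matrix(wm, gpcs, 1)
        assert np.abs(out.values).max() < 1e-12

    def test_rows_orthogonal_to_projected_components(self, gpcs, rng):
        wm = make_windows(rng.normal(size=(6, 8)))
        out = adjust_window_matrix(wm, gpcs, 3)
        assert np.abs(out.values @ gpcs.components[:3].T).max() < 1e-8

    def test_sample_order_mismatch_rejected(self, gpcs, rng):
        gpcs.sample_order = [f"s{i}" for i in range(8)]
        wm = make_windows(rng.normal(size=(2, 8)))
        wm.sample_order = [f"other{i}" for i in range(8)]
        with pytest.raises(ValueError, match="sample order"):
            adjust_window_matrix(wm, gpcs, 1)


class TestPopulationHMM:
    def test_constant_diploid_depth_calls_cn2_everywhere(self):
        wm = make_windows(np.ones((10, 6)))
        fit = fit_population_hmm(wm)
        calls = call_genotypes(fit, threshold=0.9)
        assert np.all(calls.copy_number == 2)
        assert calls.certainty == pytest.approx(np.ones(6), abs=1e-6)

    def test_single_window_matches_mixture_oracle(self, rng):
        x = np.concatenate([rng.normal(0.0, 0.02, 30).clip(min=0),
                            rng.normal(0.5, 0.03, 40),
                            rng.normal(1.0, 0.03, 30)])
        model = CopyNumberModel(em_iterations=6)
        fit = fit_population_hmm(make_windows(x[None, :]), model)
        means, variances, post = uniform_mixture_em_oracle(
            x, model.means, model.variances, n_iter=6)
        assert fit.model.means == pytest.approx(means, abs=1e-6)
        assert fit.posteriors[:, 0, :] == pytest.approx(post, abs=1e-6)

    def test_three_cluster_recovery(self, rng):
        truth = rng.choice(3, size=120, p=[0.36, 0.48, 0.16])
        levels = truth / 2.0
        values = levels[None, :] + rng.normal(0, 0.03, size=(40, 120))
        fit = fit_population_hmm(make_windows(values))
        assert fit.model.means[:3] == pytest.approx([0.0, 0.5, 1.0], abs=0.02)
        calls = call_genotypes(fit, threshold=0.9)
        acc, _ = concordance(calls, truth)
        assert acc > 0.99

    def test_em_log_likelihood_non_decreasing(self, rng):
        values = rng.choice([0.0, 0.5, 1.0], size=80)[None, :].repeat(15, axis=0)
        values = values + rng.normal(0, 0.05, size=values.shape)
        fit = fit_population_hmm(make_windows(values))
        diffs = np.diff(fit.log_likelihoods)
        assert np.all(diffs > -1e-6)

    def test_posteriors_normalized(self, rng):
        values = rng.normal(0.7, 0.3, size=(12, 9))
        fit = fit_population_hmm(make_windows(values))
        sums = fit.posteriors.sum(axis=2)
        assert sums == pytest.approx(np.ones_like(sums), abs=1e-9)

    def test_means_strictly_increasing_after_every_iteration(self, rng):
        values = rng.normal(0.5, 0.4, size=(20, 30)).clip(min=0)
        fit = fit_population_hmm(make_windows(values))
        for step in fit.iteration_trail:
            assert np.all(np.diff(step["means"]) > 0)

    def test_affine_constraint_keeps_empty_states_on_the_cn_line(self, rng):
        # only CN 0/1/2 populated; affine mode must park CN 3/4 on the line
        truth = rng.choice(3, size=200, p=[0.36, 0.48, 0.16])
        scale = np.exp(rng.normal(0, 0.08, 200))
        values = (truth / 2.0 * scale)[None, :] + rng.normal(0, 0.03, (50, 200))
        fit = fit_population_hmm(make_windows(values), mean_constraint="affine",
                                 update_start_probs=True)
        m = fit.model.means
        assert m[:3] == pytest.approx([0.0, 0.5, 1.0], abs=0.05)
        assert m[3] == pytest.approx(2 * m[2] - m[1], abs=0.1)
        calls = call_genotypes(fit, threshold=0.9)
        acc, _ = concordance(calls, truth)
        assert acc >= 0.97

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            fit_population_hmm(make_windows(np.ones((4, 1))))

    def test_unknown_constraint_rejected(self):
        with pytest.raises(ValueError, match="mean_constraint"):
            fit_population_hmm(make_windows(np.ones((2, 3))), mean_constraint="x")


class TestCallsAndConcordance:
    def _fit_like(self, mean_post):
        from exocnv.genotype import HMMFit

        post = np.asarray(mean_post, dtype=float)[:, None, :]
        return HMMFit(CopyNumberModel(), post, [0.0], [])

    def test_threshold_rule(self):
        fit = self._fit_like([
            [0.0, 0.02, 0.95, 0.03, 0.0],   # certainty 0.95 -> called
            [0.0, 0.85, 0.10, 0.05, 0.0],   # certainty 0.85 -> missing
        ])
        calls = call_genotypes(fit, threshold=0.9)
        assert list(calls.copy_number) == [2, -1]
        assert calls.missing_rate == pytest.approx(0.5)

    def test_zero_threshold_never_missing(self):
        fit = self._fit_like([[0.2, 0.21, 0.2, 0.2, 0.19]] * 4)
        calls = call_genotypes(fit, threshold=0.0)
        assert calls.missing_rate == 0.0

    def test_concordance_arithmetic(self):
        calls = GenotypeCalls([f"s{i}" for i in range(12)],
                              np.array([2] * 10 + [-1, -1]),
                              np.ones(12), 0.9)
        truth = np.array([2] * 9 + [1] + [2, 2])
        acc, miss = concordance(calls, truth)
        assert acc == pytest.approx(0.9)
        assert miss == pytest.approx(2 / 12)

    def test_all_missing_accuracy_undefined(self):
        calls = GenotypeCalls(["a", "b"], np.array([-1, -1]), np.zeros(2), 0.9)
        acc, miss = concordance(calls, {"a": 2, "b": 1})
        assert acc is None and miss == 1.0

    def test_truth_must_cover_samples(self):
        calls = GenotypeCalls(["a"], np.array([2]), np.ones(1), 0.9)
        with pytest.raises(ValueError, match="cover"):
            concordance(calls, np.array([2, 2]))


class TestViterbi:
    def test_segmentation_recovers_state_blocks(self, rng):
        path_truth = np.array([2] * 20 + [1] * 20 + [2] * 20)
        values = (path_truth / 2.0 + rng.normal(0, 0.05, 60))[:, None]
        values = np.repeat(values, 2, axis=1)
        model = CopyNumberModel()
        path = viterbi_path(values, model, sample=0)
        assert np.mean(path == path_truth) > 0.95
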