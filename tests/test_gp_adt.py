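import numpy as np
import pytest
from scipy import stats

from omtemplate.gp_adt import (
    GPHyperparams,
    GPModel,
    StratifiedTraining,
    fit_hyperparameters,
    gp_neg_log_marginal_likelihood,
    gp_predict_mean_field,
    make_age_template,
    sq_exp_kernel,
    stratify_training,
)
from omtemplate.volgeom import DisplacementField, ImageGrid

GRID4 = ImageGrid.isotropic((4, 4, 4), 2.0)


def _tiny_warps(n, seed=0, grid=GRID4):
    rng = np.random.default_rng(seed)
    return [DisplacementField(grid, rng.normal(size=grid.shape + (3,)))
            for _ in range(n)]


def _make_training(ages, counts, mean_fields, grid=GRID4, bin_width=0.5):
    return StratifiedTraining(
        ages=np.asarray(ages, float), counts=np.asarray(counts, float),
        mean_fields=np.asarray(mean_fields, float), grid=grid,
        bin_width=bin_width, n_bins=len(ages))


class TestStratify:
    def test_full_coverage_gives_148_subbins(self):
        # dense uniform coverage of [45, 82): 74 half-yearly bins x 2
        n = 74 * 32
        ages = np.linspace(45.0, 82.0, n, endpoint=False)
        training = stratify_training(ages, _tiny_warps(n), seed=0)
        assert training.n_bins == 74
        assert training.n_subbins == 148
        assert training.counts.sum() == n

    def test_weight_matrix_entries(self):
        ages = np.array([50.1, 50.2, 50.3, 50.4])
        training = stratify_training(ages, _tiny_warps(4), seed=1)
        W = training.weight_matrix
        assert np.allclose(np.diag(W), 1.0 / training.counts)
        # a sub-bin with p_l = 4 would carry 1/4 on the diagonal
        if (training.counts == 4).any():
            assert 0.25 in np.diag(W)

    def test_same_age_two_subbins(self):
        ages = np.full(10, 60.2)
        training = stratify_training(ages, _tiny_warps(10), seed=2)
        assert training.n_bins == 1
        assert training.n_subbins == 2
        assert training.counts.sum() == 10

    def test_deterministic_given_seed(self):
        ages = np.linspace(50, 55, 40)
        w = _tiny_warps(40)
        a = stratify_training(ages, w, seed=3)
        b = stratify_training(ages, w, seed=3)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.mean_fields, b.mean_fields)

    def test_subbin_mean_is_euclidean_mean(self):
        ages = np.full(6, 47.2)
        warps = _tiny_warps(6, seed=5)
        training = stratify_training(ages, warps, seed=5)
        total = training.mean_fields * training.counts[:, None, None]
        pooled = total.sum(axis=0) / training.counts.sum()
        direct = np.mean([w.disp for w in warps], axis=0).reshape(-1, 3)
        assert np.allclose(pooled, direct)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            stratify_training(np.array([]), [], seed=0)


class TestKernel:
    HYP = GPHyperparams(2.0, 0.5, 5.0)

    def test_same_point(self):
        assert sq_exp_kernel(3.0, 3.0, self.HYP) == pytest.approx(4.0)

    def test_one_length_scale(self):
        k = sq_exp_kernel(0.0, 5.0, self.HYP)
        assert k == pytest.approx(4.0 * np.exp(-0.5))

    def test_monotone_decreasing(self):
        d = np.linspace(0, 20, 50)
        k = sq_exp_kernel(0.0, d, self.HYP)
        assert np.all(np.diff(k) < 0)

    def test_positive_hyper_required(self):
        with pytest.raises(ValueError):
            GPHyperparams(1.0, -0.1, 5.0)


class TestMarginalLikelihood:
    def _instance(self, L=5, V=2, seed=0):
        rng = np.random.default_rng(seed)
        ages = np.sort(rng.uniform(45, 80, L))
        counts = rng.integers(1, 6, L).astype(float)
        fields = rng.normal(size=(L, V, 3))
        return _make_training(ages, counts, fields,
                              grid=ImageGrid.isotropic((V, 1, 1), 1.0)
                              if False else GRID4)

    def test_matches_multivariate_normal_oracle(self):
        # independent oracle: scipy multivariate_normal log-density per
        # output column (constants added back)
        rng = np.random.default_rng(7)
        L, V = 5, 2
        ages = np.sort(rng.uniform(45, 80, L))
        counts = rng.integers(1, 6, L).astype(float)
        fields = rng.normal(size=(L, V, 3))
        training = _make_training(ages, counts, fields)
        hyper = GPHyperparams(1.5, 0.7, 6.0)
        voxel_sample = np.arange(V)
        nll = gp_neg_log_marginal_likelihood(hyper, training, voxel_sample)

        K = hyper.sigma_f ** 2 * np.exp(
            -np.subtract.outer(ages, ages) ** 2 / (2 * hyper.length_scale ** 2))
        A = K + hyper.sigma_n ** 2 * np.diag(1.0 / counts)
        A[np.diag_indices_from(A)] += 1e-8 * hyper.sigma_f ** 2
        Y = fields[:, :V, :].reshape(L, -1)
        expected = 0.0
        for col in range(Y.shape[1]):
            logpdf = stats.multivariate_normal(np.zeros(L), A).logpdf(Y[:, col])
            expected += -logpdf - 0.5 * L * np.log(2 * np.pi)
        assert nll == pytest.approx(expected, abs=1e-8)

    def test_zero_outputs_leave_logdet_term(self):
        training = self._instance()
        training.mean_fields[:] = 0.0
        hyper = GPHyperparams(1.0, 0.5, 5.0)
        nll = gp_neg_log_marginal_likelihood(hyper, training)
        K = sq_exp_kernel(training.ages, training.ages, hyper)
        A = K + 0.25 * training.weight_matrix
        A[np.diag_indices_from(A)] += 1e-8
        ncomp = training.mean_fields[0].size
        assert nll == pytest.approx(0.5 * ncomp * np.linalg.slogdet(A)[1],
                                    rel=1e-9)

    def test_permutation_invariant(self):
        training = self._instance(seed=3)
        hyper = GPHyperparams(1.0, 0.5, 5.0)
        nll = gp_neg_log_marginal_likelihood(hyper, training)
        perm = np.random.default_rng(1).permutation(len(training.ages))
        shuffled = _make_training(training.ages[perm], training.counts[perm],
                                  training.mean_fields[perm])
        nll2 = gp_neg_log_marginal_likelihood(hyper, shuffled)
        assert nll2 == pytest.approx(nll, rel=1e-9)


def simulate_training(hyper: GPHyperparams, L: int, n_voxels: int, seed: int,
                      age_range=(45.0, 82.0)) -> StratifiedTraining:
    """Forward-simulate sub-bin mean fields from the GP noise model."""
    rng = np.random.default_rng(seed)
    ages = np.sort(rng.uniform(*age_range, L))
    counts = rng.integers(1, 30, L).astype(float)
    K = sq_exp_kernel(ages, ages, hyper)
    A = K + hyper.sigma_n ** 2 * np.diag(1.0 / counts)
    A[np.diag_indices_from(A)] += 1e-10
    Lchol = np.linalg.cholesky(A)
    Y = Lchol @ rng.standard_normal((L, n_voxels * 3))
    side = int(round(n_voxels ** (1 / 3)))
    grid = ImageGrid.isotropic((side, side, max(1, n_voxels // side ** 2)), 2.0)
    nv = int(np.prod(grid.shape))
    return _make_training(ages, counts, Y.reshape(L, -1)[:, :nv * 3].reshape(
        L, nv, 3), grid=grid)


class TestFitAndPredict:
    def test_fixed_seed_bitwise(self):
        hyper = GPHyperparams(2.0, 0.5, 5.0)
        training = simulate_training(hyper, L=40, n_voxels=64, seed=1)
        a = fit_hyperparameters(training, n_voxels=32, seed=9)
        b = fit_hyperparameters(training, n_voxels=32, seed=9)
        assert (a.sigma_f, a.sigma_n, a.length_scale) == \
            (b.sigma_f, b.sigma_n, b.length_scale)

    def test_recovery_small(self):
        truth = GPHyperparams(2.0, 0.5, 5.0)
        training = simulate_training(truth, L=60, n_voxels=216, seed=4)
        fit = fit_hyperparameters(training, n_voxels=216, seed=4)
        assert fit.length_scale == pytest.approx(truth.length_scale, rel=0.3)
        assert fit.sigma_f == pytest.approx(truth.sigma_f, rel=0.3)

    def test_voxel_subsample_stability(self):
        truth = GPHyperparams(2.0, 0.5, 5.0)
        training = simulate_training(truth, L=60, n_voxels=512, seed=6)
        f1 = fit_hyperparameters(training, n_voxels=128, seed=2)
        f2 = fit_hyperparameters(training, n_voxels=256, seed=2)
        assert f2.length_scale == pytest.approx(f1.length_scale, rel=0.5)

    def test_single_point_interpolation(self):
        # sigma_n -> 0: the GP interpolates the single training point
        grid = GRID4
        field = np.random.default_rng(0).normal(size=(1,) + (
            int(np.prod(grid.shape)), 3))
        training = _make_training([60.0], [5.0], field, grid=grid)
        model = GPModel(GPHyperparams(2.0, 1e-6, 5.0), training)
        pred = gp_predict_mean_field(60.0, model)
        assert np.allclose(pred.disp.reshape(-1, 3), field[0], atol=1e-5)

    def test_far_extrapolation_reverts_to_prior(self):
        hyper = GPHyperparams(2.0, 0.5, 5.0)
        training = simulate_training(hyper, L=30, n_voxels=64, seed=8)
        model = GPModel(hyper, training)
        pred = gp_predict_mean_field(training.ages.max() + 100.0, model)
        assert np.abs(pred.disp).max() <= 1e-6

    def test_extrapolation_shrinkage_monotone(self):
        hyper = GPHyperparams(2.0, 0.5, 5.0)
        training = simulate_training(hyper, L=30, n_voxels=64, seed=8)
        model = GPModel(hyper, training)
        hi = training.ages.max()
        norms = [np.linalg.norm(gp_predict_mean_field(hi + d, model).disp)
                 for d in range(1, 15)]
        assert all(b < a for a, b in zip(norms, norms[1:]))

    def test_prediction_linear_in_outputs(self):
        hyper = GPHyperparams(2.0, 0.5, 5.0)
        training = simulate_training(hyper, L=20, n_voxels=64, seed=9)
        model = GPModel(hyper, training)
        scaled = _make_training(training.ages, training.counts,
                                2.5 * training.mean_fields, grid=training.grid)
        model2 = GPModel(hyper, scaled)
        p1 = gp_predict_mean_field(55.0, model)
        p2 = gp_predict_mean_field(55.0, model2)
        assert np.allclose(p2.disp, 2.5 * p1.disp, rtol=1e-10)

    def test_weight_matrix_confidence(self):
        # two bins at equal distance from the query: the higher-count bin
        # pulls the prediction closer to its mean
        grid = GRID4
        nv = int(np.prod(grid.shape))
        y_hi = np.ones((nv, 3))
        y_lo = -np.ones((nv, 3))
        training = _make_training([50.0, 60.0], [100.0, 1.0],
                                  np.stack([y_hi, y_lo]), grid=grid)
        model = GPModel(GPHyperparams(1.0, 1.0, 10.0), training)
        pred = gp_predict_mean_field(55.0, model).disp.mean()
        assert pred > 0  # closer to the high-count bin's value (+1)

    def test_linear_trend_held_out_age(self):
        # forward-simulation oracle: linear-trend fields, predict held-out age
        rng = np.random.default_rng(12)
        grid = GRID4
        nv = int(np.prod(grid.shape))
        direction = rng.normal(size=(nv, 3))
        ages = np.arange(46.0, 80.0, 1.0)
        fields = np.stack([(a - 60.0) * 0.05 * direction for a in ages])
        fields += rng.normal(scale=0.01, size=fields.shape)
        training = _make_training(ages, np.full(len(ages), 10.0), fields,
                                  grid=grid)
        hyper = fit_hyperparameters(training, n_voxels=nv, seed=0)
        model = GPModel(hyper, training)
        target = (70.5 - 60.0) * 0.05 * direction
        pred = gp_predict_mean_field(70.5, model).disp.reshape(-1, 3)
        rms_err = np.sqrt(np.mean((pred - target) ** 2))
        rms_sig = np.sqrt(np.mean(target ** 2))
        assert rms_err <= 0.1 * rms_sig


@pytest.fixture(scope="module")
def single_subject_setup():
    from omtemplate.phantom import PhantomParams, SyntheticCohort, make_subject
    from omtemplate.template_builder import MultimodalTemplate, \
        normalize_intensity
    from omtemplate.volgeom import WeightImage

    p = PhantomParams(grid_shape=(32, 32, 32), voxel_size=3.0,
                      subject_warp_amplitude=0.0, affine_jitter=(0.0, 0.0),
                      affine_translation=0.0, noise_sd=(0.0, 0.0, 0.0))
    sub = make_subject(p, age=60.0, subject_seed=1, subject_id="s0")
    cohort = SyntheticCohort([sub], p)
    grid = sub.t1.grid
    template = MultimodalTemplate(
        t1=normalize_intensity(sub.t1, "auto"),
        flair=normalize_intensity(sub.flair, "auto"),
        dti=sub.dti.copy(),
        soft_t1_mask=WeightImage(grid, sub.brain_mask.values),
        soft_dti_mask=WeightImage(grid, sub.brain_mask.values))
    return cohort, template


class TestMakeAgeTemplate:
    def test_zero_prediction_returns_fixed_template(self, single_subject_setup):
        cohort, template = single_subject_setup
        grid = template.grid
        nv = int(np.prod(grid.shape))
        training = _make_training([60.0], [5.0], np.zeros((1, nv, 3)),
                                  grid=grid)
        model = GPModel(GPHyperparams(1.0, 0.5, 5.0), training)
        warps = {"s0": DisplacementField.zero(grid)}
        adt = make_age_template(60.0, model, template, warps, cohort)
        rel = np.abs(adt.t1.values - template.t1.values).max()
        rel /= template.t1.values.max()
        assert rel <= 1e-3

    def test_outside_range_warns(self, single_subject_setup):
        cohort, template = single_subject_setup
        grid = template.grid
        nv = int(np.prod(grid.shape))
        training = _make_training([60.0], [5.0], np.zeros((1, nv, 3)),
                                  grid=grid)
        model = GPModel(GPHyperparams(1.0, 0.5, 5.0), training)
        warps = {"s0": DisplacementField.zero(grid)}
        with pytest.warns(UserWarning, match="outside the training range"):
            make_age_template(90.0, model, template, warps, cohort)
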