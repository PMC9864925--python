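"""Classifier contract: prediction, loss, analytic gradients, SGD, serialization."""

import math

import numpy as np
import pytest

from dmflsim import (
    ClassifierModel,
    GradientVector,
    HyperParams,
    ParameterVector,
    cross_entropy_loss,
    deserialize_parameters,
    get_architecture,
    loss_gradient,
    model_size_bytes,
    predict_proba,
    serialize_parameters,
    sgd_step,
)
from dmflsim import generate_synthetic_dataset

from conftest import make_manual_dataset


def toy_linear_model(input_side=3, num_classes=5, seed=None):
    """Linear-softmax on tiny images: 3x3 x 5 classes + bias = 50 parameters."""
    arch = get_architecture("linear", (input_side, input_side), num_classes)
    if seed is None:
        params = ParameterVector(np.zeros(arch.dimensionality), "linear")
    else:
        params = arch.init_params(seed)
    return ClassifierModel(arch, params)


class TestPredictProba:
    def test_zero_parameters_give_uniform(self):
        model = toy_linear_model()
        p = predict_proba(model, np.zeros((3, 3)))
        assert np.allclose(p, 1.0 / 5)

    @pytest.mark.parametrize("arch_id,shape", [("linear", (8, 8)), ("small-cnn", (16, 16))])
    def test_probabilities_normalized(self, arch_id, shape):
        model = ClassifierModel.initialize(arch_id, shape, 4, seed=3)
        rng = np.random.default_rng(0)
        for _ in range(5):
            p = predict_proba(model, rng.uniform(size=shape))
            assert (p >= 0).all()
            assert abs(p.sum() - 1.0) < 1e-9

    def test_raising_final_bias_raises_class_probability(self):
        model = ClassifierModel.initialize("small-cnn", (16, 16), 3, seed=1)
        img = np.random.default_rng(2).uniform(size=(16, 16))
        base = predict_proba(model, img)
        v = model.parameters.values.copy()
        v[-1] += 0.5  # last entry is the final-layer bias of the last class
        bumped = predict_proba(model.with_parameters(ParameterVector(v, "small-cnn")), img)
        assert bumped[-1] > base[-1]

    def test_shape_mismatch_rejected(self):
        model = toy_linear_model()
        with pytest.raises(ValueError, match="shape"):
            predict_proba(model, np.zeros((4, 4)))


class TestCrossEntropy:
    def test_uniform_predictor_loss_is_ln_k(self):
        model = toy_linear_model()
        data = make_manual_dataset([np.zeros((3, 3))] * 4, [0, 1, 2, 3], 5)
        assert cross_entropy_loss(model, data) == pytest.approx(math.log(5), abs=1e-12)

    def test_near_perfect_predictor_loss_near_zero(self):
        arch = get_architecture("linear", (3, 3), 2)
        v = np.zeros(arch.dimensionality)
        v[-2] = 50.0  # huge bias toward class 0
        model = ClassifierModel(arch, ParameterVector(v, "linear"))
        data = make_manual_dataset([np.zeros((3, 3))] * 3, [0, 0, 0], 2)
        assert cross_entropy_loss(model, data) < 1e-12

    def test_two_sample_arithmetic_oracle(self):
        """True-class probabilities 0.5 and 0.25 give loss (ln2 + ln4)/2."""
        arch = get_architecture("linear", (3, 3), 2)
        v = np.zeros(arch.dimensionality)
        # weight on pixel 0 for class 1 = ln 3: an all-zero image gets p=(.5,.5),
        # an image with pixel0=1 gets p(class0) = 1/(1+3) = 0.25
        v[1] = math.log(3.0)  # W[pixel0, class1] in row-major (d_in, K) layout
        model = ClassifierModel(arch, ParameterVector(v, "linear"))
        x1 = np.zeros((3, 3))
        x2 = np.zeros((3, 3))
        x2[0, 0] = 1.0
        data = make_manual_dataset([x1, x2], [0, 0], 2)
        expected = (math.log(2) + math.log(4)) / 2
        assert cross_entropy_loss(model, data) == pytest.approx(expected, rel=1e-12)

    def test_empty_dataset_rejected(self, tiny_dataset):
        model = toy_linear_model()
        with pytest.raises(ValueError):
            cross_entropy_loss(model, tiny_dataset.subset([]))


class TestGradient:
    def _finite_difference(self, model, data, indices, h=1e-5):
        v = model.parameters.values
        out = {}
        for i in indices:
            vp, vm = v.copy(), v.copy()
            vp[i] += h
            vm[i] -= h
            aid = model.parameters.architecture_id
            lp = cross_entropy_loss(model.with_parameters(ParameterVector(vp, aid)), data)
            lm = cross_entropy_loss(model.with_parameters(ParameterVector(vm, aid)), data)
            out[i] = (lp - lm) / (2 * h)
        return out

    def test_toy_linear_matches_finite_differences(self):
        """50-parameter toy model: analytic vs central differences, <1e-4 rel."""
        model = toy_linear_model(seed=13)
        rng = np.random.default_rng(1)
        data = make_manual_dataset(
            [rng.uniform(size=(3, 3)) for _ in range(6)], [0, 1, 2, 3, 4, 0], 5
        )
        g = loss_gradient(model, data).values
        fd = self._finite_difference(model, data, range(g.size))
        for i, approx in fd.items():
            assert abs(g[i] - approx) <= 1e-4 * max(1e-8, abs(approx))

    def test_small_cnn_matches_finite_differences(self):
        model = ClassifierModel.initialize("small-cnn", (12, 12), 3, seed=5)
        rng = np.random.default_rng(2)
        data = make_manual_dataset([rng.uniform(size=(12, 12)) for _ in range(4)], [0, 1, 2, 1], 3)
        g = loss_gradient(model, data).values
        idx = np.random.default_rng(3).choice(g.size, 50, replace=False)
        fd = self._finite_difference(model, data, idx)
        for i, approx in fd.items():
            assert abs(g[i] - approx) <= 1e-4 * max(1e-6, abs(approx) + abs(g[i]))

    def test_duplicated_batch_has_identical_gradient(self, tiny_dataset):
        model = ClassifierModel.initialize("linear", (16, 16), 3, seed=0)
        batch = tiny_dataset.subset(range(6))
        doubled = make_manual_dataset(
            [s.pixels for s in batch] + [s.pixels for s in batch],
            list(batch.labels_array()) * 2,
            3,
        )
        g1 = loss_gradient(model, batch).values
        g2 = loss_gradient(model, doubled).values
        assert np.allclose(g1, g2, atol=1e-12)

    def test_gradient_length_matches_dimensionality(self, tiny_dataset):
        model = ClassifierModel.initialize("small-cnn", (16, 16), 3, seed=0)
        g = loss_gradient(model, tiny_dataset.subset(range(4)))
        assert g.dimensionality == model.architecture.dimensionality

    def test_one_sgd_step_decreases_convex_loss(self, tiny_dataset):
        model = ClassifierModel.initialize("linear", (16, 16), 3, seed=2)
        before = cross_entropy_loss(model, tiny_dataset)
        g = loss_gradient(model, tiny_dataset)
        stepped = model.with_parameters(sgd_step(model.parameters, g, 0.1))
        assert cross_entropy_loss(stepped, tiny_dataset) <= before


class TestSgdStep:
    def test_zero_gradient_is_identity(self):
        p = ParameterVector(np.array([1.0, -2.0]), "linear")
        out = sgd_step(p, GradientVector(np.zeros(2)), 0.5)
        assert np.array_equal(out.values, p.values)

    def test_forced_arithmetic(self):
        p = ParameterVector(np.array([1.0, 2.0]), "linear")
        out = sgd_step(p, GradientVector(np.array([0.5, -1.0])), 0.1)
        assert np.allclose(out.values, [0.95, 2.1])

    def test_quadratic_contraction_to_minimum(self):
        """On loss (w-3)^2, 100 steps at rate 0.1 converge to 3 within 1e-6."""
        w = ParameterVector(np.array([0.0]), "linear")
        for _ in range(100):
            grad = GradientVector(2.0 * (w.values - 3.0))
            w = sgd_step(w, grad, 0.1)
        assert abs(w.values[0] - 3.0) < 1e-6

    def test_dimension_mismatch_rejected(self):
        p = ParameterVector(np.array([1.0, 2.0]), "linear")
        with pytest.raises(ValueError):
            sgd_step(p, GradientVector(np.array([1.0])), 0.1)


class TestSerialization:
    def test_roundtrip_identity(self):
        rng = np.random.default_rng(4)
        p = ParameterVector(rng.normal(size=137), "small-cnn")
        q = deserialize_parameters(serialize_parameters(p))
        assert q.architecture_id == p.architecture_id
        assert np.array_equal(q.values, p.values)

    def test_byte_length_is_header_plus_8d(self):
        for d in (1, 10, 1000):
            p = ParameterVector(np.zeros(d), "linear")
            blob = serialize_parameters(p)
            header = len(blob) - 8 * d
            assert header == 8 + 2 + len("linear") + 4 + 4  # magic+len+id+dim+crc

    def test_corrupted_payload_rejected(self):
        blob = bytearray(serialize_parameters(ParameterVector(np.ones(5), "linear")))
        blob[20] ^= 0xFF
        with pytest.raises(ValueError, match="corrupt"):
            deserialize_parameters(bytes(blob))
        with pytest.raises(ValueError, match="magic"):
            deserialize_parameters(b"garbage")

    def test_sized_architectures_order_by_upload_size(self):
        sizes = {
            a: model_size_bytes(ClassifierModel.initialize(a, (32, 32), 6, seed=0))
            for a in ("vgg16-sized", "vgg19-sized", "densenet169-sized")
        }
        assert sizes["vgg16-sized"] < sizes["vgg19-sized"] < sizes["densenet169-sized"]

    def test_small_cnn_size_regression(self):
        model = ClassifierModel.initialize("small-cnn", (32, 32), 6, seed=0)
        assert model.architecture.dimensionality == 19222
        assert model_size_bytes(model) == 153803
        assert model_size_bytes(model) == len(serialize_parameters(model.parameters))

    def test_padded_architecture_trains_like_its_base(self):
        """Padding entries are inert: logits agree with the base small CNN."""
        ds = generate_synthetic_dataset([5, 5], image_size=(16, 16), seed=7)
        base = ClassifierModel.initialize("small-cnn", (16, 16), 2, seed=9)
        padded = ClassifierModel.initialize("vgg16-sized", (16, 16), 2, seed=9)
        pb = predict_proba(base, ds.samples[0])
        pp = predict_proba(padded, ds.samples[0])
        assert np.allclose(pb, pp)
        g = loss_gradient(padded, ds)
        assert np.allclose(g.values[base.architecture.dimensionality :], 0.0)


class TestHyperParams:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            HyperParams(learning_rate=0.0)
        with pytest.raises(ValueError):
            HyperParams(batch_size=0)
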