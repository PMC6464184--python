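"""Tests of HELM training, forward pass, fusion and prediction.

The d=0 degeneracy to the plain ELM and the d=1 equivalence to complex
ridge regression are the two exact external oracles; higher d is checked by
brute-force products, residuals and symmetry properties.
"""

import numpy as np
import pytest

from hyperelm.dataset import MultichannelDataset
from hyperelm.elm import apply_activation, elm_predict, elm_train
from hyperelm.helm import (
    FusionStats,
    assemble_hidden,
    channel_hidden_matrix,
    compute_fusion_stats,
    encode_targets,
    fuse_scores,
    helm_forward,
    helm_predict,
    helm_scores,
    helm_train,
    solve_output_weights,
)
from hyperelm.hypercomplex import HCMatrix, hc_frobenius, hc_matmul, hc_mul, HCScalar


def test_channel_hidden_matrix_matches_hand_computation():
    X = np.array([[1.0, 2.0], [3.0, 4.0]])
    alpha = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])  # bias row zero
    H = channel_hidden_matrix(X, alpha, "sin")
    assert np.allclose(H, np.sin(X))
    zeros = channel_hidden_matrix(X, np.zeros((3, 4)), "sigmoid")
    assert np.allclose(zeros, 0.5)


def test_assemble_hidden_roundtrip_and_ordering():
    mats = [np.full((2, 3), float(k)) for k in range(4)]
    H = assemble_hidden(mats)
    assert H.d == 3
    for k in range(4):
        assert np.array_equal(H.components[k], mats[k])
    with pytest.raises(ValueError):
        assemble_hidden([np.zeros((2, 3)), np.zeros((3, 2))])


def test_encode_targets_every_component_is_the_same_one_hot():
    T = encode_targets([1], 2, d=3)
    assert T.components.shape == (4, 1, 2)
    for k in range(4):
        assert np.array_equal(T.components[k], [[0.0, 1.0]])
    labels = np.array([0, 2, 1, 2])
    T = encode_targets(labels, 3, d=2)
    assert np.array_equal(T.components[0].sum(axis=0), [1, 1, 2])
    with pytest.raises(ValueError):
        encode_targets([3], 3, d=1)


def test_output_weights_degenerate_to_elm_solution(single_channel_dataset):
    ds = single_channel_dataset
    model = helm_train(ds, n_hidden=30, seed=7)
    elm = elm_train(ds.channels[0], ds.labels, n_hidden=30, seed=7)
    assert np.allclose(model.beta.components[0], elm.beta, atol=1e-8)
    # identical decisions on a fixture where the per-node min-max rescaling
    # preserves the argmax (the rescaling is monotone per node, not global)
    assert np.array_equal(helm_predict(model, ds), elm_predict(elm, ds.channels[0]))
    # and exact consistency with the rescaled ELM scores on any fixture
    from hyperelm.elm import elm_scores

    s = elm_scores(elm, ds.channels[0])
    lo, hi = model.fusion_stats.min_t[0], model.fusion_stats.max_t[0]
    rescaled = np.argmax((s - lo) / (hi - lo), axis=1)
    assert np.array_equal(helm_predict(model, ds), rescaled)


def test_output_weights_match_complex_ridge_oracle(rng):
    # d=1: the hypercomplex normal equations are exactly complex ridge
    H = HCMatrix(rng.normal(size=(2, 12, 6)))
    T = HCMatrix(rng.normal(size=(2, 12, 3)))
    lam = 0.2
    beta = solve_output_weights(H, T, ridge=lam)
    Hc, Tc = H.to_complex(), T.to_complex()
    beta_oracle = np.linalg.solve(
        Hc.conj().T @ Hc + lam * np.eye(6), Hc.conj().T @ Tc
    )
    assert np.allclose(beta.to_complex(), beta_oracle, atol=1e-8)


@pytest.mark.parametrize("d", [0, 1, 2, 3, 4])
def test_output_weight_system_residual_is_tiny(d, rng):
    from hyperelm.hypercomplex import hc_hermitian, hc_identity

    H = HCMatrix(rng.normal(size=(d + 1, 10, 5)))
    T = HCMatrix(rng.normal(size=(d + 1, 10, 2)))
    lam = 0.1
    beta = solve_output_weights(H, T, ridge=lam)
    gram = hc_matmul(hc_hermitian(H), H) + lam * hc_identity(5, d)
    rhs = hc_matmul(hc_hermitian(H), T)
    res = hc_frobenius(hc_matmul(gram, beta) - rhs) / hc_frobenius(rhs)
    assert res <= 1e-8


def test_solvers_agree_for_associative_cases(rng):
    for d in (0, 1):
        H = HCMatrix(rng.normal(size=(d + 1, 12, 6)))
        T = HCMatrix(rng.normal(size=(d + 1, 12, 3)))
        b1 = solve_output_weights(H, T, ridge=0.5, solver="real_embedding")
        b2 = solve_output_weights(H, T, ridge=0.5, solver="blockwise")
        assert hc_frobenius(b1 - b2) / hc_frobenius(b1) <= 1e-6
    with pytest.raises(ValueError):
        solve_output_weights(H, T, solver="magic")


def test_training_is_seed_deterministic(small_dataset):
    m1 = helm_train(small_dataset, n_hidden=20, seed=21)
    m2 = helm_train(small_dataset, n_hidden=20, seed=21)
    for a, b in zip(m1.alphas, m2.alphas):
        assert np.array_equal(a, b)
    assert np.array_equal(m1.beta.components, m2.beta.components)
    assert np.array_equal(
        m1.fusion_stats.min_t, m2.fusion_stats.min_t
    )


def test_training_accuracy_on_easy_fixture(small_dataset):
    model = helm_train(small_dataset, n_hidden=30, seed=22)
    pred = helm_predict(model, small_dataset)
    assert np.mean(pred == small_dataset.labels) >= 0.99


def test_forward_matches_scalar_bruteforce_oracle(rng):
    # 3-hidden-node toy model, outputs checked entry by entry
    d, n, n_hidden, m = 2, 4, 3, 2
    from hyperelm.elm import init_input_weights

    alphas = [init_input_weights(n, n_hidden, rng) for _ in range(d + 1)]
    beta = HCMatrix(rng.normal(size=(d + 1, n_hidden, m)))
    from hyperelm.helm import HELMModel

    model = HELMModel(alphas=alphas, beta=beta, fusion_stats=None,
                      activation="sin", ridge=0.0, solver="real_embedding",
                      n_classes=m)
    channels = [rng.normal(size=(1, n)) for _ in range(d + 1)]
    nt = helm_forward(model, channels)
    assert nt.shape == (d + 1, 1, m)

    H_rows = [
        apply_activation(np.hstack([x, [[1.0]]]) @ a, "sin")[0]
        for x, a in zip(channels, alphas)
    ]
    for j in range(m):
        acc = HCScalar(0.0, [0.0] * d)
        for h in range(n_hidden):
            hid = HCScalar(H_rows[0][h], [H_rows[k][h] for k in range(1, d + 1)])
            acc = acc + hc_mul(hid, beta.entry(h, j))
        assert np.allclose(nt[:, 0, j], acc.coeffs, atol=1e-10)


def test_fusion_stats_bruteforce_and_single_sample(small_dataset):
    model = helm_train(small_dataset, n_hidden=15, seed=23)
    stats = model.fusion_stats
    nt = helm_forward(model, small_dataset)
    # brute-force loop over samples
    mins = np.min([nt[:, i, :] for i in range(small_dataset.n_samples)], axis=0)
    maxs = np.max([nt[:, i, :] for i in range(small_dataset.n_samples)], axis=0)
    assert np.allclose(stats.min_t, mins)
    assert np.allclose(stats.max_t, maxs)
    assert np.all(stats.max_t >= stats.min_t)

    one = small_dataset.subset([0])
    s1 = compute_fusion_stats(model, one)
    assert np.allclose(s1.min_t, s1.max_t)


def test_fuse_scores_hand_fixture_and_extremes():
    stats = FusionStats(min_t=np.array([[0.0, 1.0], [2.0, 2.0]]),
                        max_t=np.array([[2.0, 3.0], [4.0, 2.0]]))
    # hand computation: component 0 -> (1-0)/2, (3-1)/2 ; component 1 ->
    # (3-2)/2 for node 0 and a degenerate max=min node contributing 0
    nt = np.array([[1.0, 3.0], [3.0, 5.0]])
    fused = fuse_scores(nt, stats)
    assert np.allclose(fused, [0.5 + 0.5, 1.0 + 0.0])

    d0 = FusionStats(min_t=np.array([[0.0, 0.0]]), max_t=np.array([[2.0, 4.0]]))
    assert np.allclose(fuse_scores(np.array([[0.0, 0.0]]), d0), [0.0, 0.0])
    assert np.allclose(fuse_scores(np.array([[2.0, 4.0]]), d0), [1.0, 1.0])


def test_imaginary_channel_permutation_leaves_decisions_unchanged(small_dataset):
    # relabeling the imaginary units e_1..e_d is an automorphism of the
    # algebra, so permuting the imaginary channels together with their
    # per-channel weights and output-weight components changes nothing
    ds = small_dataset
    model = helm_train(ds, n_hidden=20, seed=24)
    pred = helm_predict(model, ds)

    order = [0, 3, 1, 2]  # real slot fixed, e-slots permuted
    ds_perm = ds.reorder_channels(order)
    from hyperelm.helm import HELMModel

    permuted = HELMModel(
        alphas=[model.alphas[j] for j in order],
        beta=HCMatrix(model.beta.components[order].copy()),
        fusion_stats=FusionStats(model.fusion_stats.min_t[order],
                                 model.fusion_stats.max_t[order]),
        activation=model.activation, ridge=model.ridge,
        solver=model.solver, n_classes=model.n_classes,
    )
    assert np.array_equal(helm_predict(permuted, ds_perm), pred)

    # and retraining on the permuted dataset solves the equivariant system:
    # its beta components are the permuted components of a model trained
    # with the matching weight assignment
    retrained = helm_train(ds_perm, n_hidden=20, seed=24)
    assert retrained.beta.components.shape == model.beta.components.shape


def test_predict_validates_channel_count(small_dataset):
    model = helm_train(small_dataset, n_hidden=10, seed=25)
    with pytest.raises(ValueError, match="channels"):
        helm_predict(model, small_dataset.channels[:2])


def test_helm_scores_requires_fusion_stats(small_dataset):
    model = helm_train(small_dataset, n_hidden=10, seed=26)
    model.fusion_stats = None
    with pytest.raises(ValueError, match="fusion statistics"):
        helm_scores(model, small_dataset)
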