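"""Framework pipelines: classifier head, OMP, CA/CA-CA/RL/RL-A/CL contracts."""

import numpy as np
import pytest
from sklearn.linear_model import orthogonal_mp

import ecgca
from ecgca import pipelines
from ecgca.sensing import Measurement


# ---------------------------------------------------------------------------
# SVM head
# ---------------------------------------------------------------------------


def test_classifier_separates_two_clouds(rng):
    X = np.vstack([rng.normal(0, 0.1, (30, 3)), rng.normal(5, 0.1, (30, 3))])
    y = np.array([0] * 30 + [1] * 30)
    model = ecgca.train_classifier(X, y)
    assert np.mean(model.classifier.predict(X) == y) == 1.0
    assert model.n_support == len(model.classifier.support_)


def test_classifier_grid_choice_is_deterministic(rng):
    X = rng.normal(size=(50, 4))
    y = np.arange(50) % 2
    a = ecgca.train_classifier(X, y)
    b = ecgca.train_classifier(X, y)
    assert (a.C, a.gamma) == (b.C, b.gamma)
    assert a.C in pipelines.SVM_C_GRID
    assert any(np.isclose(a.gamma, g) for g in pipelines.SVM_GAMMA_GRID)


def test_classifier_rejects_single_class(rng):
    with pytest.raises(ValueError):
        ecgca.train_classifier(rng.normal(size=(10, 2)), np.zeros(10))


def test_classifier_on_well_separated_metadata(rng):
    """22 classes whose means are >= 10 noise-sd apart: near-perfect held-out."""
    means = rng.normal(0, 5.0, size=(22, 8))
    sd = 0.1  # mean separation ~ 5 >> 10 * sd
    Xtr = np.vstack([m + rng.normal(0, sd, (20, 8)) for m in means])
    ytr = np.repeat(np.arange(22), 20)
    Xte = np.vstack([m + rng.normal(0, sd, (10, 8)) for m in means])
    yte = np.repeat(np.arange(22), 10)
    model = ecgca.train_classifier(Xtr, ytr)
    acc = 100 * np.mean(model.classifier.predict(Xte) == yte)
    assert acc >= 95.0


# ---------------------------------------------------------------------------
# OMP
# ---------------------------------------------------------------------------


def test_omp_single_atom_exact(rng):
    theta = rng.normal(size=(20, 40))
    y = 3.0 * theta[:, 7]
    code = ecgca.omp_reconstruct(theta, y, K=4)
    assert code.support == (7,)
    assert code.coefficients[7] == pytest.approx(3.0)
    assert np.count_nonzero(code.coefficients) == 1
    assert code.residual_norm == pytest.approx(0.0, abs=1e-9)


def test_omp_zero_input_empty_support(rng):
    code = ecgca.omp_reconstruct(rng.normal(size=(10, 20)), np.zeros(10), K=5)
    assert code.support == ()
    np.testing.assert_array_equal(code.coefficients, 0.0)


def test_omp_argument_errors(rng):
    theta = rng.normal(size=(10, 20))
    with pytest.raises(ValueError):
        ecgca.omp_reconstruct(theta, np.zeros(10), K=11)
    theta[:, 3] = 0.0
    with pytest.raises(ValueError):
        ecgca.omp_reconstruct(theta, np.zeros(10), K=2)


def test_omp_matches_independent_solver(rng):
    """Cross-check coefficients against sklearn's OMP on random instances."""
    for _ in range(20):
        theta = rng.normal(size=(30, 60))
        theta /= np.linalg.norm(theta, axis=0)
        s0 = np.zeros(60)
        s0[rng.choice(60, 4, replace=False)] = rng.normal(size=4)
        y = theta @ s0
        ours = ecgca.omp_reconstruct(theta, y, K=4, tol=0.0)
        theirs = orthogonal_mp(theta, y, n_nonzero_coefs=4)
        np.testing.assert_allclose(ours.coefficients, theirs, atol=1e-8)


def test_omp_residual_tolerance_stops_early(rng):
    theta = rng.normal(size=(20, 40))
    y = 2.0 * theta[:, 5]
    code = ecgca.omp_reconstruct(theta, y, K=10, tol=1e-6)
    assert len(code.support) == 1  # residual hits zero after one atom


# ---------------------------------------------------------------------------
# CA / CA-CA
# ---------------------------------------------------------------------------


def test_ca_reduces_to_eigenspace_rotation_without_compression(
    aligned_noiseless_dataset,
):
    """M = N, Phi = I, orthonormal Psi: metadata is exactly Psi^T x."""
    ds = aligned_noiseless_dataset
    phi = ecgca.SensingMatrix(entries=np.eye(250), seed=0)
    model, psi = ecgca.ca_offline(ds, L=20, phi=phi)
    assert psi.basis.shape == (250, 20)
    x = ds.test.segments[0].samples
    s = ecgca.project_metadata(model.projector, phi.entries @ x)
    np.testing.assert_allclose(s, psi.basis.T @ x, atol=1e-8)


def test_ca_online_accuracy_on_aligned_noiseless_fixture(
    aligned_noiseless_dataset, phi_half
):
    ds = aligned_noiseless_dataset
    model, psi = ecgca.ca_offline(ds, L=20, phi=phi_half)
    acc = ecgca.evaluate_framework(model, ds, phi_half)
    assert acc >= 95.0


def test_ca_online_tag_check_and_purity(small_dataset, phi_half):
    model, psi = ecgca.ca_offline(small_dataset, L=15, phi=phi_half)
    test = small_dataset.test
    xhat = ecgca.compress_matrix(phi_half, test.signal_matrix())
    batch = ecgca.predict_measurements(model, xhat)
    singles = [
        ecgca.ca_online(Measurement(xhat[:, i]), phi_half, psi, model)
        for i in range(xhat.shape[1])
    ]
    np.testing.assert_array_equal(batch, singles)
    with pytest.raises(ValueError, match="tag"):
        ecgca.caca_online(Measurement(xhat[:, 0]), phi_half, psi, model)


def test_caca_equals_ca_when_peaks_are_centered():
    """Pre-centered windows + identity sensing: R_p = I, so CA-CA == CA."""
    tpl = ecgca.make_subject_template(1, 5)
    shift0 = (125 - tpl.r_center) % 250  # land the R peak on ceil(N/2)
    ds = ecgca.generate_dataset(
        3, 15, 5, shift_range=(0, 0), noise_sd=0.0, rng_seed=6, beat_jitter=0.0
    )
    # recenter every window exactly
    segs = [ecgca.time_align(s)[0] for s in ds.segments]
    ds = ecgca.LabeledDataset(segs, ds.splits, ds.seed, ds.params)
    phi = ecgca.SensingMatrix(entries=np.eye(250), seed=0)
    ca_model, _ = ecgca.ca_offline(ds, L=12, phi=phi)
    caca_model, psi = ecgca.caca_offline(ds, L=12, phi=phi)
    X = ds.train.signal_matrix()
    s_ca = (ca_model.projector @ (phi.entries @ X)).T
    peaks = ecgca.estimate_peak_indices(phi, phi.entries @ X)
    assert np.all(peaks == 125)
    s_caca = np.stack(
        [caca_model.cache.get(125).theta_pinv @ (phi.entries @ X[:, i])
         for i in range(X.shape[1])]
    )
    np.testing.assert_allclose(s_caca, s_ca, atol=1e-8)


def test_caca_prediction_is_shift_invariant():
    """A window and its circular shift get the same label (noiseless, Phi=I
    so the compressed peak estimate is exact)."""
    ds = ecgca.generate_dataset(3, 20, 5, noise_sd=0.0, rng_seed=14,
                                beat_jitter=0.0)
    phi = ecgca.SensingMatrix(entries=np.eye(250), seed=0)
    model, psi = ecgca.caca_offline(ds, L=15, phi=phi)
    seg = ds.test.segments[0]
    labels = set()
    for k in (0, 31, 125, 200):
        x = np.roll(seg.samples, k)
        labels.add(ecgca.caca_online(Measurement(phi.entries @ x), phi, psi, model))
    assert len(labels) == 1


def test_caca_online_matches_offline_metadata(small_dataset, phi_half):
    model, psi = ecgca.caca_offline(small_dataset, L=15, phi=phi_half)
    seg = small_dataset.train.segments[0]
    xhat = ecgca.compress(phi_half, seg)
    p = ecgca.estimate_peak_index(phi_half, xhat)
    s_online = model.cache.get(p).metadata(xhat)
    # recompute through the aligned-projection formula directly
    shift = ecgca.circular_shift_matrix(250, p)
    s_direct = ecgca.aligned_projection(phi_half, shift, psi).metadata(xhat)
    np.testing.assert_allclose(s_online, s_direct, atol=1e-10)


def test_reconstruction_free_paths_never_invoke_omp(
    small_dataset, phi_half, monkeypatch
):
    def _forbidden(*args, **kwargs):  # pragma: no cover
        raise AssertionError("reconstruction called on a compressive-analysis path")

    monkeypatch.setattr(pipelines, "omp_reconstruct", _forbidden)
    ca_model, psi = ecgca.ca_offline(small_dataset, L=10, phi=phi_half)
    caca_model, _ = ecgca.caca_offline(small_dataset, L=10, phi=phi_half)
    xhat = ecgca.compress_matrix(phi_half, small_dataset.test.signal_matrix())
    ecgca.predict_measurements(ca_model, xhat)
    ecgca.predict_measurements(caca_model, xhat)
    ecgca.ca_online(Measurement(xhat[:, 0]), phi_half, psi, ca_model)
    ecgca.caca_online(Measurement(xhat[:, 0]), phi_half, psi, caca_model)


# ---------------------------------------------------------------------------
# RL / RL-A / CL
# ---------------------------------------------------------------------------


def test_sparsifying_basis_is_square_orthonormal():
    B = ecgca.dct_basis(250)
    assert B.shape == (250, 250)
    np.testing.assert_allclose(B.T @ B, np.eye(250), atol=1e-10)


def test_rl_at_full_sampling_reconstructs_exactly():
    """CR 1.0 with K = N: OMP drives the residual to zero and RL reduces to
    time-domain classification."""
    rng = np.random.default_rng(3)
    phi = ecgca.SensingMatrix(entries=rng.normal(size=(250, 250)) / 15.8, seed=3)
    B = ecgca.dct_basis(250)
    tpl = ecgca.make_subject_template(1, 2)
    x = ecgca.render_segment(tpl, 10, 0.0, 0).samples
    code = ecgca.omp_reconstruct(phi.entries @ B, phi.entries @ x, K=250, tol=1e-10)
    np.testing.assert_allclose(B @ code.coefficients, x, atol=1e-6)


def test_rl_alignment_improves_on_misaligned_fixture(phi_half):
    ds = ecgca.generate_dataset(4, 40, 15, rng_seed=17)
    rl = ecgca.rl_offline(ds, phi_half, align=False)
    rla = ecgca.rl_offline(ds, phi_half, align=True)
    assert rl.framework == "rl" and rla.framework == "rl-a"
    acc_rl = ecgca.evaluate_framework(rl, ds, phi_half)
    acc_rla = ecgca.evaluate_framework(rla, ds, phi_half)
    assert acc_rla > acc_rl


def test_cl_feature_dimension_is_m(small_dataset, phi_half):
    model = ecgca.cl_offline(small_dataset, phi_half)
    assert model.n_features == phi_half.M
    xhat = ecgca.compress_matrix(phi_half, small_dataset.test.signal_matrix())
    assert ecgca.cl_online(Measurement(xhat[:, 0]), model) in \
        small_dataset.subject_ids()


def test_cl_comparable_to_ca_on_aligned_noiseless_fixture(
    aligned_noiseless_dataset, phi_half
):
    ds = aligned_noiseless_dataset
    cl = ecgca.cl_offline(ds, phi_half)
    ca, _ = ecgca.ca_offline(ds, L=20, phi=phi_half)
    acc_cl = ecgca.evaluate_framework(cl, ds, phi_half)
    acc_ca = ecgca.evaluate_framework(ca, ds, phi_half)
    assert abs(acc_cl - acc_ca) <= 3.0


def test_framework_feature_dimension_contracts(small_dataset, phi_half):
    ca, _ = ecgca.ca_offline(small_dataset, L=15, phi=phi_half)
    assert ca.n_features == 15
    cl = ecgca.cl_offline(small_dataset, phi_half)
    with pytest.raises(ValueError, match="features"):
        pipelines._predict(cl, np.zeros(250))


def test_pipeline_determinism(small_dataset, phi_half):
    a, _ = ecgca.ca_offline(small_dataset, L=12, phi=phi_half)
    b, _ = ecgca.ca_offline(small_dataset, L=12, phi=phi_half)
    xhat = ecgca.compress_matrix(phi_half, small_dataset.test.signal_matrix())
    np.testing.assert_array_equal(
        ecgca.predict_measurements(a, xhat), ecgca.predict_measurements(b, xhat)
    )
    assert (a.C, a.gamma) == (b.C, b.gamma)


def test_fit_framework_dispatch_and_errors(small_dataset, phi_half):
    with pytest.raises(ValueError, match="unknown framework"):
        ecgca.fit_framework("svm", small_dataset, phi_half)
    with pytest.raises(ValueError):
        ecgca.ca_offline(small_dataset, L=130, phi=phi_half)  # L > M
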