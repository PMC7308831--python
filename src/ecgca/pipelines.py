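"""The five identification frameworks and the shared SVM head.

Reconstruction-free paths (the method under study):

* CA    — compressive analysis: metadata s = Theta^+ x-hat with Theta = Phi Psi,
          classifier trained on s.
* CA-CA — compressed-alignment-aided CA: per segment, estimate the R-peak p
          from Phi^T x-hat, rotate the dictionary by R_p, and classify the
          aligned metadata s_a = (Phi R_p^T Psi)^+ x-hat.

Reconstruction baselines:

* RL    — reconstruct x from x-hat by OMP against a cosine sparsifying basis,
          classify the N-dimensional reconstruction.
* RL-A  — RL plus exact time-domain alignment of the reconstruction.
* CL    — compressed learning: classify the raw M-dimensional measurements.

All frameworks share one RBF-SVM head selected by 5-fold cross-validated grid
search over C in {1, 5, 10} and gamma in {1e-4, ..., 1} (log-spaced), the
one-vs-one multiclass scheme of libsvm.  Feature dimensions are part of each
framework's contract (N for RL/RL-A, M for CL, L for CA/CA-CA) and are
asserted at train and predict time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import idct
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from . import alignment as _alignment
from .alignment import ProjectorCache, estimate_peak_indices
from .eigenspace import PCADictionary, eigenspace_projector, fit_pca_dictionary
from .sensing import Measurement, SensingMatrix, compress_matrix, time_align
from .synthetic import ECGSegment, LabeledDataset

FRAMEWORKS = ("rl", "rl-a", "cl", "ca", "ca-ca")

SVM_C_GRID = (1, 5, 10)
SVM_GAMMA_GRID = tuple(np.logspace(-4, 0, 5))
SVM_CV_FOLDS = 5

DEFAULT_TOL = 1e-6


@dataclass
class IdentModel:
    """A trained identification model plus the projection context needed online."""

    framework: str
    classifier: SVC
    n_features: int
    C: float
    gamma: float
    phi: SensingMatrix | None = None
    psi: PCADictionary | None = None
    projector: np.ndarray | None = None  # Theta^+ (CA)
    cache: ProjectorCache | None = None  # aligned projectors keyed by p (CA-CA)
    basis: np.ndarray | None = None  # N x dR sparsifying basis (RL/RL-A)
    sparsity: int | None = None  # OMP K (RL/RL-A)
    extras: dict = field(default_factory=dict)

    @property
    def n_support(self) -> int:
        """Unique support vectors across the one-vs-one binary machines."""
        return int(len(self.classifier.support_))


@dataclass(frozen=True)
class SparseCode:
    """Output of OMP: a K-sparse coefficient vector over a dR-atom dictionary."""

    coefficients: np.ndarray  # length dR; exactly zero off the support
    support: tuple[int, ...]  # selected atom indices, in selection order
    residual_norm: float


def _check_features(model: IdentModel, features: np.ndarray) -> None:
    if features.shape[-1] != model.n_features:
        raise ValueError(
            f"{model.framework} model expects {model.n_features}-dimensional "
            f"features, got {features.shape[-1]}"
        )


def _check_tag(model: IdentModel, expected: str) -> None:
    if model.framework != expected:
        raise ValueError(
            f"model framework tag is '{model.framework}', expected '{expected}'"
        )


def train_classifier(
    features, labels, framework: str = "ca", **context
) -> IdentModel:
    """Fit the shared RBF-SVM head by cross-validated grid search.

    Ties in mean CV accuracy resolve to the first (C, gamma) pair in
    row-major grid order; folds are the deterministic (unshuffled) stratified
    split, so the selected pair is reproducible for identical inputs.
    Extra keyword arguments (phi, psi, projector, ...) are stored on the model.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_samples, n_features) matching labels")
    if np.unique(y).size < 2:
        raise ValueError("training requires at least 2 classes")
    search = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": list(SVM_C_GRID), "gamma": list(SVM_GAMMA_GRID)},
        cv=StratifiedKFold(n_splits=SVM_CV_FOLDS),
        n_jobs=None,
    )
    search.fit(X, y)
    best = search.best_estimator_
    return IdentModel(
        framework=framework,
        classifier=best,
        n_features=X.shape[1],
        C=float(search.best_params_["C"]),
        gamma=float(search.best_params_["gamma"]),
        **context,
    )


def _predict(model: IdentModel, features: np.ndarray) -> np.ndarray:
    _check_features(model, features)
    return model.classifier.predict(np.atleast_2d(features))


# ---------------------------------------------------------------------------
# CA — compressive analysis (Algorithms: offline fits Psi on RAW signals at the
# transmitter side, then trains on compressed-domain metadata)
# ---------------------------------------------------------------------------


def ca_offline(
    dataset: LabeledDataset, L: int, phi: SensingMatrix
) -> tuple[IdentModel, PCADictionary]:
    """Offline CA: Psi = PCA-D(X, L); s = (Phi Psi)^+ Phi x per window."""
    train = dataset.train
    if len(train) == 0:
        raise ValueError("training split is empty")
    X = train.signal_matrix()
    psi = fit_pca_dictionary(X, L)
    _, theta_pinv = eigenspace_projector(phi, psi)
    metadata = (theta_pinv @ compress_matrix(phi, X)).T
    model = train_classifier(
        metadata, train.labels(), framework="ca", phi=phi, psi=psi,
        projector=theta_pinv,
    )
    return model, psi


def ca_online(
    xhat: Measurement, phi: SensingMatrix, psi: PCADictionary, model: IdentModel
) -> int:
    """Online CA: one matrix-vector product, then the classifier."""
    _check_tag(model, "ca")
    theta_pinv = model.projector
    if theta_pinv is None:
        _, theta_pinv = eigenspace_projector(phi, psi)
    s = theta_pinv @ np.asarray(xhat.values, dtype=float)
    return int(_predict(model, s)[0])


# ---------------------------------------------------------------------------
# CA-CA — compressed-alignment-aided compressive analysis
# ---------------------------------------------------------------------------


def caca_offline(
    dataset: LabeledDataset, L: int, phi: SensingMatrix
) -> tuple[IdentModel, PCADictionary]:
    """Offline CA-CA: per window, estimate p, rotate, project, then train.

    The aligned projector depends on the window only through p, which takes
    at most N values; projectors are cached by p with identical semantics to
    the per-window recomputation.
    """
    train = dataset.train
    if len(train) == 0:
        raise ValueError("training split is empty")
    X = train.signal_matrix()
    psi = fit_pca_dictionary(X, L)
    if psi.L > phi.M:
        raise ValueError(
            f"aligned eigenspace projection requires L <= M (L={psi.L}, M={phi.M})"
        )
    xhat = compress_matrix(phi, X)
    peaks = estimate_peak_indices(phi, xhat)
    cache = ProjectorCache(phi, psi)
    metadata = np.empty((xhat.shape[1], psi.L))
    for p in np.unique(peaks):
        proj = cache.get(int(p))
        cols = peaks == p
        metadata[cols] = (proj.theta_pinv @ xhat[:, cols]).T
    model = train_classifier(
        metadata, train.labels(), framework="ca-ca", phi=phi, psi=psi, cache=cache,
    )
    return model, psi


def caca_online(
    xhat: Measurement, phi: SensingMatrix, psi: PCADictionary, model: IdentModel
) -> int:
    """Online CA-CA: p -> R_p -> Theta_a^+ -> s_a -> label, reconstruction-free."""
    _check_tag(model, "ca-ca")
    cache = model.cache if model.cache is not None else ProjectorCache(phi, psi)
    p = _alignment.estimate_peak_index(phi, xhat)
    s_a = cache.get(p).metadata(xhat)
    return int(_predict(model, s_a)[0])


# ---------------------------------------------------------------------------
# OMP and the reconstruction baselines
# ---------------------------------------------------------------------------


def omp_reconstruct(
    theta: np.ndarray, xhat, K: int, tol: float = DEFAULT_TOL
) -> SparseCode:
    """Orthogonal matching pursuit against the columns of theta (M x dR).

    Greedily selects the column most correlated (normalized) with the current
    residual, re-solves least squares on the accumulated support, and stops
    after K atoms or once the residual norm drops below ``tol``.
    """
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(getattr(xhat, "values", xhat), dtype=float)
    m, d_r = theta.shape
    if K > m:
        raise ValueError(f"sparsity K={K} exceeds measurement count M={m}")
    if K < 0:
        raise ValueError("sparsity K must be non-negative")
    col_norms = np.linalg.norm(theta, axis=0)
    if np.any(col_norms == 0):
        raise ValueError("dictionary contains a zero column")

    support: list[int] = []
    coef = np.zeros(d_r)
    residual = y.copy()
    available = np.ones(d_r, dtype=bool)
    while len(support) < K and np.linalg.norm(residual) > tol:
        corr = np.abs(theta.T @ residual) / col_norms
        corr[~available] = -np.inf
        j = int(np.argmax(corr))
        support.append(j)
        available[j] = False
        sub = theta[:, support]
        sol, *_ = np.linalg.lstsq(sub, y, rcond=None)
        residual = y - sub @ sol
    if support:
        coef[support] = sol
    return SparseCode(
        coefficients=coef,
        support=tuple(support),
        residual_norm=float(np.linalg.norm(residual)),
    )


def dct_basis(n: int) -> np.ndarray:
    """Orthonormal cosine synthesis basis (N x N): x = B s, B^T B = I."""
    return idct(np.eye(n), axis=0, norm="ortho")


def _reconstruct_batch(
    phi: SensingMatrix, basis: np.ndarray, xhat: np.ndarray, K: int, tol: float
) -> np.ndarray:
    theta = phi.entries @ basis
    recon = np.empty((basis.shape[0], xhat.shape[1]))
    for i in range(xhat.shape[1]):
        code = omp_reconstruct(theta, xhat[:, i], K, tol)
        recon[:, i] = basis @ code.coefficients
    return recon


def default_sparsity(m: int) -> int:
    """Default OMP sparsity K = floor(M/4)."""
    return max(1, m // 4)


def rl_offline(
    dataset: LabeledDataset,
    phi: SensingMatrix,
    align: bool = False,
    K: int | None = None,
    tol: float = DEFAULT_TOL,
) -> IdentModel:
    """Reconstructed learning: OMP-reconstruct every training window, then
    (optionally) time-align the reconstruction, and train on the N-dim signals."""
    train = dataset.train
    if len(train) == 0:
        raise ValueError("training split is empty")
    basis = dct_basis(phi.N)
    K = default_sparsity(phi.M) if K is None else K
    xhat = compress_matrix(phi, train.signal_matrix())
    recon = _reconstruct_batch(phi, basis, xhat, K, tol)
    if align:
        for i in range(recon.shape[1]):
            aligned, _ = time_align(ECGSegment(recon[:, i], 0))
            recon[:, i] = aligned.samples
    return train_classifier(
        recon.T, train.labels(), framework="rl-a" if align else "rl",
        phi=phi, basis=basis, sparsity=K, extras={"tol": tol},
    )


def rl_online(xhat: Measurement, phi: SensingMatrix, model: IdentModel) -> int:
    """Online RL / RL-A: reconstruct, optionally align, classify."""
    if model.framework not in ("rl", "rl-a"):
        raise ValueError(f"model framework tag is '{model.framework}', expected rl/rl-a")
    code = omp_reconstruct(
        phi.entries @ model.basis, xhat, model.sparsity,
        model.extras.get("tol", DEFAULT_TOL),
    )
    x_rec = model.basis @ code.coefficients
    if model.framework == "rl-a":
        aligned, _ = time_align(ECGSegment(x_rec, 0))
        x_rec = aligned.samples
    return int(_predict(model, x_rec)[0])


# ---------------------------------------------------------------------------
# CL — compressed learning
# ---------------------------------------------------------------------------


def cl_offline(dataset: LabeledDataset, phi: SensingMatrix) -> IdentModel:
    """Compressed learning: classifier straight on the M-dim measurements."""
    train = dataset.train
    if len(train) == 0:
        raise ValueError("training split is empty")
    xhat = compress_matrix(phi, train.signal_matrix())
    return train_classifier(xhat.T, train.labels(), framework="cl", phi=phi)


def cl_online(xhat: Measurement, model: IdentModel) -> int:
    _check_tag(model, "cl")
    return int(_predict(model, np.asarray(xhat.values, dtype=float))[0])


# ---------------------------------------------------------------------------
# Uniform dispatch used by benchmarks and the CLI
# ---------------------------------------------------------------------------


def fit_framework(
    framework: str,
    dataset: LabeledDataset,
    phi: SensingMatrix,
    L: int = 39,
    K: int | None = None,
) -> IdentModel:
    """Train any framework on the dataset's training split."""
    if framework == "ca":
        model, _ = ca_offline(dataset, L, phi)
    elif framework == "ca-ca":
        model, _ = caca_offline(dataset, L, phi)
    elif framework == "cl":
        model = cl_offline(dataset, phi)
    elif framework in ("rl", "rl-a"):
        model = rl_offline(dataset, phi, align=framework == "rl-a", K=K)
    else:
        raise ValueError(f"unknown framework '{framework}' (choose from {FRAMEWORKS})")
    return model


def predict_measurements(model: IdentModel, xhat: np.ndarray) -> np.ndarray:
    """Batch online inference from an M x m measurement matrix.

    Semantically the map of the single-measurement online operation over the
    columns; vectorized per framework for speed.
    """
    phi, psi = model.phi, model.psi
    if model.framework == "cl":
        return _predict(model, xhat.T)
    if model.framework == "ca":
        return _predict(model, (model.projector @ xhat).T)
    if model.framework == "ca-ca":
        cache = model.cache if model.cache is not None else ProjectorCache(phi, psi)
        peaks = estimate_peak_indices(phi, xhat)
        meta = np.empty((xhat.shape[1], psi.L))
        for p in np.unique(peaks):
            cols = peaks == p
            meta[cols] = (cache.get(int(p)).theta_pinv @ xhat[:, cols]).T
        return _predict(model, meta)
    if model.framework in ("rl", "rl-a"):
        recon = _reconstruct_batch(
            phi, model.basis, xhat, model.sparsity, model.extras.get("tol", DEFAULT_TOL)
        )
        if model.framework == "rl-a":
            for i in range(recon.shape[1]):
                aligned, _ = time_align(ECGSegment(recon[:, i], 0))
                recon[:, i] = aligned.samples
        return _predict(model, recon.T)
    raise ValueError(f"unknown framework '{model.framework}'")


def evaluate_framework(
    model: IdentModel, dataset: LabeledDataset, phi: SensingMatrix
) -> float:
    """Test-split identification accuracy (percent) of a trained model."""
    from .evaluation import identification_accuracy

    test = dataset.test
    xhat = compress_matrix(phi, test.signal_matrix())
    preds = predict_measurements(model, xhat)
    return identification_accuracy(preds, test.labels())
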