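"""PCA-assisted dictionary learning and least-squares metadata projection.

Instead of an iteratively learned sparse dictionary, the sparsifying basis is
the eigenbasis of the training data: the covariance

    Sigma = (1/m) (X - xbar h)(X - xbar h)^T,      X in R^{N x m},

is eigendecomposed (Sigma = U V U^T, eigenvalues sorted non-increasing) and
the dictionary Psi is the first L columns of U.  One dictionary is shared by
all subjects.  A compressed measurement x-hat = Phi x is mapped to its
low-dimensional "metadata" by ordinary least squares against Theta = Phi Psi:

    s = (Theta^T Theta)^{-1} Theta^T x-hat = Theta^+ x-hat,

a single matrix-vector product online — no sparse coding, no reconstruction.

Note the projection model x-hat = Phi Psi s carries no mean term: the training
mean xbar enters the covariance but is deliberately not subtracted when
projecting.  It is retained on the dictionary for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

#: Gram condition number above which the normal equations are abandoned for an
#: SVD pseudo-inverse.
GRAM_COND_LIMIT = 1e8

#: condition number beyond which Theta is treated as numerically rank-deficient.
RANK_DEFICIENT_COND = 1e14


@dataclass(frozen=True)
class PCADictionary:
    """The N x L eigenbasis Psi with its full eigenvalue spectrum.

    ``eigenvalues`` is the complete length-N non-increasing spectrum of the
    training covariance (diag of V); ``basis`` keeps only the leading L
    eigenvectors.  ``train_mean`` is the training mean xbar (diagnostic only;
    the projection model does not subtract it).
    """

    basis: np.ndarray  # N x L, orthonormal columns
    eigenvalues: np.ndarray  # length N, non-increasing
    train_mean: np.ndarray  # length N

    @property
    def N(self) -> int:
        return self.basis.shape[0]

    @property
    def L(self) -> int:
        return self.basis.shape[1]


def _as_signal_matrix(x) -> np.ndarray:
    """Accept an N x m ndarray, a LabeledDataset, or a list of segments."""
    if hasattr(x, "signal_matrix"):
        return x.signal_matrix()
    if isinstance(x, (list, tuple)):
        return np.column_stack([np.asarray(getattr(s, "samples", s)) for s in x])
    return np.asarray(x, dtype=float)


def fit_pca_dictionary(x, L: int) -> PCADictionary:
    """Learn the shared PCA-assisted dictionary from raw training windows.

    ``x`` may be an N x m matrix (columns = windows), a LabeledDataset, or a
    list of segments.  Eigenvectors are given a deterministic sign (largest-
    magnitude entry positive) since eigendecomposition is sign-ambiguous.
    """
    X = _as_signal_matrix(x)
    n, m = X.shape
    if m < 2:
        raise ValueError(f"need at least 2 training windows, got {m}")
    if not 1 <= L <= n:
        raise ValueError(f"dictionary length L must lie in [1, {n}], got {L}")

    xbar = X.mean(axis=1)
    centered = X - xbar[:, None]
    sigma = (centered @ centered.T) / m
    eigenvalues, U = np.linalg.eigh(sigma)  # ascending
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    U = U[:, order]
    # deterministic sign: largest-|entry| of each eigenvector made positive
    anchor = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[anchor, np.arange(n)])
    signs[signs == 0] = 1.0
    U = U * signs
    return PCADictionary(basis=U[:, :L], eigenvalues=eigenvalues, train_mean=xbar)


def select_components(eigenvalues: np.ndarray, energy_fraction: float) -> int:
    """Smallest L whose leading eigenvalues capture ``energy_fraction`` of the
    total eigenvalue mass (energy-threshold alternative to a fixed L)."""
    if not 0 < energy_fraction <= 1:
        raise ValueError("energy_fraction must lie in (0, 1]")
    ev = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    total = ev.sum()
    if total == 0:
        return 1
    return int(np.searchsorted(np.cumsum(ev) / total, energy_fraction) + 1)


def build_projector(theta: np.ndarray) -> np.ndarray:
    """Least-squares projector Theta^+ = (Theta^T Theta)^{-1} Theta^T.

    Solved through the normal equations with a Cholesky factorization while
    the Gram matrix is well conditioned, falling back to an SVD pseudo-inverse
    above ``GRAM_COND_LIMIT``; a numerically rank-deficient Theta raises with
    the offending condition number.
    """
    theta = np.asarray(theta, dtype=float)
    gram = theta.T @ theta
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > RANK_DEFICIENT_COND:
        raise np.linalg.LinAlgError(
            f"projection operator is rank deficient (Gram condition number {cond:.3e})"
        )
    if cond <= GRAM_COND_LIMIT:
        return cho_solve(cho_factor(gram), theta.T)
    return np.linalg.pinv(theta)


def project_metadata(theta_pinv: np.ndarray, xhat) -> np.ndarray:
    """Metadata s = Theta^+ x-hat, the minimizer of ||x-hat - Theta s||_2."""
    values = np.asarray(getattr(xhat, "values", xhat), dtype=float)
    return theta_pinv @ values


def eigenspace_projector(phi, psi: PCADictionary) -> tuple[np.ndarray, np.ndarray]:
    """Unaligned projection pair (Theta, Theta^+) with Theta = Phi Psi."""
    entries = getattr(phi, "entries", phi)
    if psi.L > entries.shape[0]:
        raise ValueError(
            "eigenspace projection requires at least as many measurements as "
            f"retained components (L={psi.L} > M={entries.shape[0]})"
        )
    theta = entries @ psi.basis
    return theta, build_projector(theta)
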