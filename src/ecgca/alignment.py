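"""Compressed-domain R-peak alignment.

The alignment reference point is the R-peak.  For a raw window x the peak
index p is found directly; for a compressed measurement x-hat = Phi x the
peak is *estimated* without reconstruction through the correlation
Phi^T x-hat, whose j-th entry approximates x_j because the Gram matrix of an
i.i.d. Gaussian sensing operator concentrates around the identity.  The
window is then rotated by the circular-shift permutation R_p so the peak
lands at the center index ceil(N/2), and the eigenspace projection is formed
against the rotated dictionary:

    Theta_a = Phi R_p^T Psi,     s_a = Theta_a^+ x-hat.

Indexing: peak indices p are 1-based (p in [1, N]) to match the matrix
formulas; array positions inside the implementation are the native 0-based
ones, related by position = p - 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .eigenspace import build_projector, project_metadata

if TYPE_CHECKING:  # pragma: no cover
    from .eigenspace import PCADictionary
    from .sensing import Measurement, SensingMatrix


def center_index(n: int) -> int:
    """1-based alignment target index, ceil(N/2)."""
    return -(-n // 2)


@dataclass(frozen=True)
class CircularShift:
    """The permutation R_p rotating a length-N window so index p is centered.

    Stored as its integer offset = (ceil(N/2) - p) mod N; applying the shift
    moves entry i (1-based) to entry ((i - 1 + offset) mod N) + 1.  The dense
    permutation matrix is materialized only on demand (tests, diagnostics).
    """

    n: int
    p: int  # 1-based reference (peak) index
    offset: int

    def apply(self, x: np.ndarray) -> np.ndarray:
        """R_p x — rotate so the reference index lands at ceil(N/2)."""
        return np.roll(x, self.offset, axis=0)

    def apply_inverse(self, x: np.ndarray) -> np.ndarray:
        """R_p^T x — undo the rotation."""
        return np.roll(x, -self.offset, axis=0)

    def matrix(self) -> np.ndarray:
        """Dense N x N permutation matrix R_p (row-rotated identity)."""
        return np.roll(np.eye(self.n), self.offset, axis=0)


def circular_shift_matrix(n: int, p: int) -> CircularShift:
    """Build R_p for reference index p (1-based).

    The two-branch definition (offset = ceil(N/2) - p for p <= ceil(N/2),
    plus N otherwise) collapses to the single formula
    offset = (ceil(N/2) - p) mod N.
    """
    if not 1 <= p <= n:
        raise ValueError(f"reference index p must lie in [1, {n}], got {p}")
    return CircularShift(n=n, p=p, offset=(center_index(n) - p) % n)


def estimate_peak_index(phi: "SensingMatrix", xhat: "Measurement") -> int:
    """Estimate the R-peak location from a measurement, without reconstruction.

    Returns the 1-based argmax of Phi^T x-hat (smallest index on ties; an
    all-zero measurement therefore yields 1).  This is an approximation of
    the raw-signal argmax — no exactness is guaranteed, only statistical
    concentration; see the Monte-Carlo accuracy tests.
    """
    correlation = phi.entries.T @ np.asarray(xhat.values, dtype=float)
    return int(np.argmax(correlation)) + 1


def estimate_peak_indices(phi: "SensingMatrix", xhat_matrix: np.ndarray) -> np.ndarray:
    """Vectorized `estimate_peak_index` over the columns of an M x m batch."""
    correlation = phi.entries.T @ np.asarray(xhat_matrix, dtype=float)
    return np.argmax(correlation, axis=0) + 1


@dataclass(frozen=True)
class AlignedProjection:
    """The aligned eigenspace projection Theta_a = Phi R_p^T Psi and its
    pseudo-inverse Theta_a^+ = (Theta_a^T Theta_a)^-1 Theta_a^T."""

    theta: np.ndarray  # M x L
    theta_pinv: np.ndarray  # L x M
    p: int

    def metadata(self, xhat: "Measurement | np.ndarray") -> np.ndarray:
        values = getattr(xhat, "values", xhat)
        return project_metadata(self.theta_pinv, values)


def aligned_projection(
    phi: "SensingMatrix", shift: CircularShift, psi: "PCADictionary"
) -> AlignedProjection:
    """Form Theta_a = Phi R_p^T Psi and its least-squares projector.

    Phi R_p^T is realized as a column rotation of Phi (cost O(MN), no dense
    permutation matrix).  Requires L <= M so the Gram matrix can be full rank.
    """
    m, n = phi.entries.shape
    if psi.basis.shape[0] != n or shift.n != n:
        raise ValueError("sensing matrix, shift, and dictionary dimensions disagree")
    if psi.L > m:
        raise ValueError(
            "aligned eigenspace projection requires at least as many "
            f"measurements as retained components (L={psi.L} > M={m})"
        )
    # column k of Phi R_p^T is column (k - offset) mod N of Phi
    phi_rotated = np.roll(phi.entries, shift.offset, axis=1)
    theta = phi_rotated @ psi.basis
    return AlignedProjection(theta=theta, theta_pinv=build_projector(theta), p=shift.p)


class ProjectorCache:
    """Cache of AlignedProjection keyed by p (at most N distinct values).

    The aligned projector is recomputed per segment in the reference
    algorithm; since only N distinct rotations exist, caching is exact.
    """

    def __init__(self, phi: "SensingMatrix", psi: "PCADictionary"):
        self.phi = phi
        self.psi = psi
        self._cache: dict[int, AlignedProjection] = {}

    def get(self, p: int) -> AlignedProjection:
        if p not in self._cache:
            shift = circular_shift_matrix(self.phi.N, p)
            self._cache[p] = aligned_projection(self.phi, shift, self.psi)
        return self._cache[p]
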