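"""Compressive sensing of ECG windows and ground-truth time-domain alignment.

A single M x N random Gaussian operator Phi performs simultaneous sampling
and compression, x-hat = Phi x.  Entries are i.i.d. N(0, 1/M) so that
E||Phi x||^2 = ||x||^2: column norms concentrate at 1 and pairwise distances
are approximately preserved (Johnson-Lindenstrauss behavior), which is what
makes learning in the measurement domain possible at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import center_index, circular_shift_matrix
from .synthetic import ECGSegment


@dataclass(frozen=True)
class SensingMatrix:
    """The M x N compressive sensing operator Phi with its provenance."""

    entries: np.ndarray
    seed: int
    distribution: str = "gaussian"

    @property
    def M(self) -> int:
        return self.entries.shape[0]

    @property
    def N(self) -> int:
        return self.entries.shape[1]

    @property
    def compression_ratio(self) -> float:
        return self.M / self.N


@dataclass(frozen=True)
class Measurement:
    """One compressed window x-hat = Phi x (length M)."""

    values: np.ndarray
    sensing_seed: int | None = None

    @property
    def m(self) -> int:
        return self.values.shape[0]


def make_sensing_matrix(m: int, n: int, seed: int) -> SensingMatrix:
    """Draw the random Gaussian Phi with i.i.d. N(0, 1/M) entries."""
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= M <= N, got M={m}, N={n}")
    entries = np.random.default_rng(seed).normal(0.0, np.sqrt(1.0 / m), size=(m, n))
    return SensingMatrix(entries=entries, seed=seed)


def compress(phi: SensingMatrix, x: "ECGSegment | np.ndarray") -> Measurement:
    """x-hat = Phi x, the exact matrix-vector product."""
    samples = np.asarray(getattr(x, "samples", x), dtype=float)
    if samples.shape[0] != phi.N:
        raise ValueError(f"segment length {samples.shape[0]} != sensing N {phi.N}")
    return Measurement(values=phi.entries @ samples, sensing_seed=phi.seed)


def compress_matrix(phi: SensingMatrix, signals: np.ndarray) -> np.ndarray:
    """Batch form: Phi X for an N x m column-stacked signal matrix."""
    if signals.shape[0] != phi.N:
        raise ValueError(f"signal dimension {signals.shape[0]} != sensing N {phi.N}")
    return phi.entries @ signals


def time_align(x: ECGSegment) -> tuple[ECGSegment, int]:
    """Ground-truth time-domain alignment of a raw window.

    The reference point is the maximum-|amplitude| sample (the R-peak;
    smallest index on ties), 1-based.  The window is rotated by the circular
    shift permutation so the peak lands at index ceil(N/2).  Returns the
    aligned segment and the detected peak index p of the *input*.
    """
    samples = np.asarray(x.samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot align an empty segment")
    p = int(np.argmax(np.abs(samples))) + 1
    shift = circular_shift_matrix(samples.shape[0], p)
    aligned = ECGSegment(
        samples=shift.apply(samples),
        subject_id=x.subject_id,
        true_peak_index=center_index(samples.shape[0])
        if x.true_peak_index is not None
        else None,
    )
    return aligned, p
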