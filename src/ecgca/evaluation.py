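"""Accuracy metric, online-stage memory accounting, and benchmark sweeps.

Memory is counted in stored real coefficients (matrix/vector elements), the
unit in which the published per-framework budgets are stated:

========  =============================================  =================
tag       formula                                        stored objects
========  =============================================  =================
rl-a      (M + N)·dR + nSV·N                             Phi, sparsifying
                                                         basis, SVM
cl        nSV·M                                          SVM only
ca-ca     (M + kd)·N + kd·M + nSV·kd                     alignment resource
                                                         Phi & Psi, projector,
                                                         SVM
ca        kd·M + nSV·kd  (repository-defined)            projector, SVM
========  =============================================  =================

where N is the window dimension, M the measurement count, dR the sparsifying
dictionary length, kd the retained PCA components, and nSV the number of
unique SVM support vectors.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pipelines import (
    FRAMEWORKS,
    default_sparsity,
    evaluate_framework,
    fit_framework,
)
from .sensing import make_sensing_matrix
from .synthetic import (
    DEFAULT_BEAT_JITTER,
    DEFAULT_NOISE_SD,
    N_DEFAULT,
    generate_dataset,
)


def identification_accuracy(predictions, truth) -> float:
    """Percent of predictions matching the true subject labels."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape or predictions.size == 0:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    return 100.0 * float(np.mean(predictions == truth))


@dataclass(frozen=True)
class MemorySpec:
    """Problem sizes entering the online-stage memory formulas."""

    N: int | None = None
    M: int | None = None
    dR: int | None = None
    kd: int | None = None
    K: int | None = None
    nSV: int | None = None

    def require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"memory formula requires field '{name}'")
            if value < 0:
                raise ValueError(f"memory field '{name}' must be non-negative")


def memory_footprint(framework: str, spec: MemorySpec) -> int:
    """Exact online-stage element count for a framework (see module table).

    The 'ca' formula has no published counterpart and is repository-defined;
    'rl' shares the 'rl-a' formula (alignment stores nothing extra).
    """
    tag = framework.lower()
    if tag in ("rl", "rl-a"):
        spec.require("M", "N", "dR", "nSV")
        return (spec.M + spec.N) * spec.dR + spec.nSV * spec.N
    if tag == "cl":
        spec.require("M", "nSV")
        return spec.nSV * spec.M
    if tag == "ca-ca":
        spec.require("M", "N", "kd", "nSV")
        return (spec.M + spec.kd) * spec.N + spec.kd * spec.M + spec.nSV * spec.kd
    if tag == "ca":
        spec.require("M", "kd", "nSV")
        return spec.kd * spec.M + spec.nSV * spec.kd
    raise ValueError(f"unknown framework tag '{framework}'")


def format_element_count(count: int) -> str:
    """Human-readable K/M rendering (K = 10^3, M = 10^6), e.g. '0.21 M'.

    Counts from 10^5 upward are shown in M (so 205 580 renders as 0.21 M,
    the style the memory-budget comparisons use), smaller ones in K.
    """
    if count >= 10**5:
        value, unit = count / 10**6, "M"
    elif count >= 10**3:
        value, unit = count / 10**3, "K"
    else:
        return str(int(count))
    text = f"{value:.2f}".rstrip("0").rstrip(".")
    return f"{text} {unit}"


def model_memory_spec(model, L: int | None = None) -> MemorySpec:
    """MemorySpec of a trained model, with nSV read off the classifier."""
    phi = model.phi
    return MemorySpec(
        N=None if phi is None else phi.N,
        M=None if phi is None else phi.M,
        dR=None if model.basis is None else model.basis.shape[1],
        kd=None if model.psi is None else model.psi.L,
        K=model.sparsity,
        nSV=model.n_support,
    )


@dataclass
class BenchmarkConfig:
    """One sweep: frameworks x compression ratios x training sizes x seeds.

    Each (CR, n_train, seed) cell shares a single dataset and sensing matrix
    across all frameworks, so per-cell comparisons are paired.
    """

    frameworks: tuple[str, ...] = ("cl", "ca-ca")
    compression_ratios: tuple[float, ...] = (0.5,)
    train_sizes: tuple[int, ...] = (200,)
    seeds: tuple[int, ...] = (0,)
    n_subjects: int = 10
    n_test: int = 80
    L: int = 39
    K: int | None = None
    noise_sd: float = DEFAULT_NOISE_SD
    beat_jitter: float = DEFAULT_BEAT_JITTER
    shift_range: tuple[int, int] | None = None
    n_samples: int = N_DEFAULT
    record_timing: bool = True

    def validate(self) -> None:
        for fw in self.frameworks:
            if fw not in FRAMEWORKS:
                raise ValueError(f"unknown framework '{fw}'")
        for cr in self.compression_ratios:
            if not 0 < cr <= 1:
                raise ValueError(f"compression ratio must lie in (0, 1], got {cr}")
        if any(s <= 0 for s in self.train_sizes):
            raise ValueError("train sizes must be positive")


@dataclass
class BenchmarkResult:
    """Sweep rows plus the configuration that produced them."""

    table: pd.DataFrame
    config: BenchmarkConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "benchmark.csv", index=False)
        manifest = asdict(self.config)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def benchmark_sweep(config: BenchmarkConfig) -> BenchmarkResult:
    """Run every sweep cell end-to-end and collect accuracy/memory rows.

    Wall-clock seconds are recorded for information only; they are hardware-
    dependent and never asserted anywhere.
    """
    config.validate()
    rows = []
    n = config.n_samples
    for seed in config.seeds:
        for n_train in config.train_sizes:
            dataset = generate_dataset(
                config.n_subjects,
                n_train,
                config.n_test,
                shift_range=config.shift_range,
                noise_sd=config.noise_sd,
                rng_seed=seed,
                n_samples=n,
                beat_jitter=config.beat_jitter,
            )
            for cr in config.compression_ratios:
                m = max(1, round(cr * n))
                phi = make_sensing_matrix(m, n, seed=seed + 1)
                for fw in config.frameworks:
                    t0 = time.perf_counter()
                    model = fit_framework(fw, dataset, phi, L=config.L, K=config.K)
                    accuracy = evaluate_framework(model, dataset, phi)
                    elapsed = time.perf_counter() - t0
                    spec = model_memory_spec(model)
                    rows.append(
                        {
                            "framework": fw,
                            "compression_ratio": cr,
                            "n_train": n_train,
                            "seed": seed,
                            "accuracy_pct": accuracy,
                            "memory_elements": memory_footprint(fw, spec),
                            "n_support": model.n_support,
                            "C": model.C,
                            "gamma": model.gamma,
                            "wall_clock_s": elapsed if config.record_timing else None,
                        }
                    )
    return BenchmarkResult(table=pd.DataFrame(rows), config=config)
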