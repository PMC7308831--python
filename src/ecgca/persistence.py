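"""Model/dataset persistence as directory bundles with JSON manifests.

A model bundle holds the fitted classifier (joblib), dense matrix files for
the sensing matrix / dictionary / sparsifying basis with JSON sidecars, and
a manifest tying them together; reloading reproduces predictions exactly.
Datasets are exchanged as CSV (one row per segment: label then N samples)
with a sidecar recording seed and generator parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np

from .alignment import ProjectorCache
from .eigenspace import PCADictionary
from .pipelines import IdentModel
from .sensing import SensingMatrix
from .synthetic import ECGSegment, LabeledDataset


def save_model(model: IdentModel, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "framework": model.framework,
        "n_features": model.n_features,
        "C": model.C,
        "gamma": model.gamma,
        "n_support": model.n_support,
        "sparsity": model.sparsity,
        "extras": model.extras,
    }
    joblib.dump(model.classifier, outdir / "classifier.joblib")
    if model.phi is not None:
        np.save(outdir / "phi.npy", model.phi.entries)
        manifest["phi"] = {
            "M": model.phi.M,
            "N": model.phi.N,
            "seed": model.phi.seed,
            "distribution": model.phi.distribution,
        }
    if model.psi is not None:
        np.save(outdir / "psi.npy", model.psi.basis)
        np.save(outdir / "psi_eigenvalues.npy", model.psi.eigenvalues)
        np.save(outdir / "psi_mean.npy", model.psi.train_mean)
        manifest["psi"] = {"N": model.psi.N, "L": model.psi.L}
    if model.projector is not None:
        np.save(outdir / "projector.npy", model.projector)
    if model.basis is not None:
        np.save(outdir / "basis.npy", model.basis)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(indir: str | Path) -> IdentModel:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    classifier = joblib.load(indir / "classifier.joblib")
    phi = psi = projector = basis = cache = None
    if "phi" in manifest:
        phi = SensingMatrix(
            entries=np.load(indir / "phi.npy"),
            seed=manifest["phi"]["seed"],
            distribution=manifest["phi"]["distribution"],
        )
    if "psi" in manifest:
        psi = PCADictionary(
            basis=np.load(indir / "psi.npy"),
            eigenvalues=np.load(indir / "psi_eigenvalues.npy"),
            train_mean=np.load(indir / "psi_mean.npy"),
        )
    if (indir / "projector.npy").exists():
        projector = np.load(indir / "projector.npy")
    if (indir / "basis.npy").exists():
        basis = np.load(indir / "basis.npy")
    if manifest["framework"] == "ca-ca" and phi is not None and psi is not None:
        cache = ProjectorCache(phi, psi)  # rebuilt lazily; projections are exact
    return IdentModel(
        framework=manifest["framework"],
        classifier=classifier,
        n_features=manifest["n_features"],
        C=manifest["C"],
        gamma=manifest["gamma"],
        phi=phi,
        psi=psi,
        projector=projector,
        cache=cache,
        basis=basis,
        sparsity=manifest["sparsity"],
        extras=manifest.get("extras", {}),
    )


def save_dataset(dataset: LabeledDataset, outdir: str | Path) -> None:
    """Write train.csv/test.csv (label, then N samples per row) + metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for split in ("train", "test"):
        sub = dataset.subset(split)
        if len(sub) == 0:
            continue
        rows = np.column_stack([sub.labels()[:, None], sub.signal_matrix().T])
        np.savetxt(outdir / f"{split}.csv", rows, delimiter=",", fmt="%.10g")
    meta = {"seed": dataset.seed, "params": dataset.params}
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_dataset(indir: str | Path) -> LabeledDataset:
    indir = Path(indir)
    meta = json.loads((indir / "metadata.json").read_text())
    segments: list[ECGSegment] = []
    splits: list[str] = []
    for split in ("train", "test"):
        path = indir / f"{split}.csv"
        if not path.exists():
            continue
        rows = np.atleast_2d(np.loadtxt(path, delimiter=","))
        for row in rows:
            segments.append(ECGSegment(row[1:].copy(), int(row[0]), None))
            splits.append(split)
    return LabeledDataset(segments, splits, seed=meta.get("seed"),
                          params=meta.get("params", {}))
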