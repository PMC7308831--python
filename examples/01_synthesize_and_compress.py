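"""Generate synthetic multi-subject ECG windows and compressively sense them.

Each subject has a fixed PQRST morphology; every rendered beat is circularly
misaligned, morphologically jittered, noisy, and normalized to [-1, 1].
A random Gaussian matrix then maps each 250-sample window to 125
measurements (compression ratio 0.5) in a single matrix-vector product.
"""

import numpy as np

import ecgca

dataset = ecgca.generate_dataset(n_subjects=4, n_train=20, n_test=5, rng_seed=0)
print(f"dataset: {len(dataset)} windows, subjects {dataset.subject_ids()}, "
      f"{len(dataset.train)} train / {len(dataset.test)} test")

seg = dataset.train.segments[0]
print(f"first window: subject {seg.subject_id}, N = {seg.n} samples, "
      f"max |amplitude| = {np.max(np.abs(seg.samples)):.3f}, "
      f"true R-peak at sample {seg.true_peak_index}")

phi = ecgca.make_sensing_matrix(m=125, n=250, seed=1)
xhat = ecgca.compress(phi, seg)
print(f"compressed to M = {xhat.m} measurements "
      f"(CR = {phi.compression_ratio}); ||x|| = {np.linalg.norm(seg.samples):.3f}, "
      f"||x-hat|| = {np.linalg.norm(xhat.values):.3f}")
print("The norms nearly agree because the N(0, 1/M) entries make the "
      "projection distance-preserving on average.")
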