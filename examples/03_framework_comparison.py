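"""Compare identification frameworks on one paired synthetic benchmark.

All frameworks see the same dataset and the same sensing matrix: compressed
learning (CL) classifies raw measurements, compressive analysis with
compressed alignment (CA-CA) classifies aligned eigenspace metadata, and
reconstructed learning with alignment (RL-A) first reconstructs via OMP.
A small cell (5 subjects, 60 train / 20 test per class) keeps this quick;
the accuracy ordering matches the full-scale benchmark.
"""

import ecgca

config = ecgca.BenchmarkConfig(
    frameworks=("cl", "ca", "ca-ca", "rl-a"),
    compression_ratios=(0.5,),
    train_sizes=(60,),
    seeds=(0,),
    n_subjects=5,
    n_test=20,
    L=39,
)
result = ecgca.benchmark_sweep(config)
cols = ["framework", "accuracy_pct", "n_support", "memory_elements"]
print(result.table[cols].to_string(index=False))
print()
print("CA-CA matches the reconstruction baseline's accuracy without ever "
      "reconstructing; the unaligned frameworks (CL, CA) pay for the "
      "misalignment with much lower accuracy.  At this toy scale the fixed "
      "alignment-resource matrices dominate CA-CA's footprint; with "
      "realistically large support-vector counts the nSV terms dominate and "
      "CA-CA is the smallest (see 04_memory_accounting.py).")
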