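"""Online-stage memory budgets of the frameworks at the published sizes.

Counts are stored real coefficients: sensing matrix, dictionary/projection
matrices, and SVM support vectors, at N=250, M=125 (CR 0.5), dR=250, kd=39
with the published support-vector counts.
"""

import ecgca

cases = [
    ("rl-a", ecgca.MemorySpec(N=250, M=125, dR=250, nSV=4920)),
    ("cl", ecgca.MemorySpec(M=125, nSV=8689)),
    ("ca-ca", ecgca.MemorySpec(N=250, M=125, kd=39, nSV=4095)),
]
for tag, spec in cases:
    count = ecgca.memory_footprint(tag, spec)
    print(f"{tag:>5}: {count:>9,} elements  ({ecgca.format_element_count(count)})")

caca = ecgca.memory_footprint("ca-ca", cases[2][1])
cl = ecgca.memory_footprint("cl", cases[1][1])
rla = ecgca.memory_footprint("rl-a", cases[0][1])
print(f"\nCA-CA needs {rla / caca:.1f}x less memory than RL-A "
      f"and {cl / caca:.1f}x less than CL.")
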