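# Methods

## Problem and model

A wearable single-lead ECG sensor acquires each 1-s heartbeat window
x ∈ ℝᴺ (N = 250 samples at 250 Hz, amplitude-normalized to [−1, 1]) through
compressive sensing: a fixed random matrix Φ ∈ ℝᴹˣᴺ (M < N) yields the
measurement x̂ = Φx, combining sampling and compression in one linear map.
The task is to identify which enrolled subject produced x̂.

The method this package implements avoids reconstructing x. Offline, the
raw training windows X ∈ ℝᴺˣᵐ (all subjects pooled) define a covariance
Σ = (1/m)(X − x̄h)(X − x̄h)ᵀ whose leading L eigenvectors form a shared
*PCA-assisted dictionary* Ψ ∈ ℝᴺˣᴸ. Online, a measurement is mapped to its
L-dimensional *metadata* by least squares against Θ = ΦΨ:

    s = (ΘᵀΘ)⁻¹Θᵀ x̂ = Θ⁺ x̂,

a single L×M matrix-vector product, and s feeds an RBF-SVM ("compressive
analysis", CA).

Because heartbeat windows arrive with arbitrary segmentation offsets, and a
random projection destroys time-domain structure, alignment must happen in
the compressed domain. The R-peak (maximum-|amplitude| deflection) is
estimated from the correlation

    p ≈ argmax (Φᵀ x̂),

valid because the Gram matrix of an i.i.d. N(0, 1/M) ensemble concentrates
at the identity, so Φᵀx̂ ≈ x entrywise. The circular-shift permutation R_p
(offset (⌈N/2⌉ − p) mod N) would rotate x so its peak lands at ⌈N/2⌉; since
only x̂ is available, the rotation is applied to the dictionary instead:

    Θₐ = Φ R_pᵀ Ψ,    sₐ = Θₐ⁺ x̂.

Classifying sₐ is the full method (CA-CA). Comparison frameworks: CL (SVM
on x̂ directly), RL (OMP reconstruction against an orthonormal cosine basis,
SVM on the reconstruction), RL-A (RL plus exact time-domain alignment of the
reconstruction).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| N | 250 | one second at 250 Hz |
| M | ⌈CR·N⌉, CR = 0.5 in benchmarks | measurement count; CR sweepable 0.1–0.9 |
| L (= kd) | 39 | retained eigenvectors; 250×39 is 15.6 % of a square dictionary. An energy-threshold selector (`select_components`) is provided as an alternative |
| K | ⌊M/4⌋ | OMP sparsity for the reconstruction baselines; residual tolerance 1e−6 |
| SVM grid | C ∈ {1, 5, 10}, γ ∈ {1e−4 … 1} (5 log-spaced), 5-fold CV | the γ range endpoint values are fixed; 5 log-spaced points sample it |
| Φ entries | i.i.d. N(0, 1/M) | makes E‖Φx‖² = ‖x‖², so distance-preservation checks are scale-free; the variance convention is a package choice (only "random Gaussian" is prescribed) |

## Indexing and numerical conventions

- Peak indices p are 1-based in the public API, matching the matrix
  formulas; internally position = p − 1. The alignment target is
  ⌈N/2⌉ (= 125 for N = 250). Argmax ties break to the smallest index.
- The two-branch circular-shift offset definition equals the single formula
  (⌈N/2⌉ − p) mod N; the permutation is applied as an O(N) index roll, and
  the dense matrix is materialized only in tests/diagnostics.
- Eigenvectors get a deterministic sign (largest-|entry| positive);
  near-duplicate eigenvalues are accepted as-is without subspace
  canonicalization, so dictionaries are only unique up to such degeneracies.
- The projection model x̂ = ΦΨs carries no mean term: x̄ enters the
  covariance but is not subtracted when projecting (the training-phase
  algorithm computes x̄, the projection equations never use it; we follow
  the projection equations). x̄ is kept on the dictionary for diagnostics.
- Θ⁺ solves the normal equations by Cholesky while cond(ΘᵀΘ) ≤ 1e8, then
  falls back to an SVD pseudo-inverse; condition numbers beyond 1e14 raise.
- Aligned projectors depend on the window only through p ∈ {1…N}, so they
  are cached by p — exact, not an approximation.
- An all-zero measurement yields p = 1 by the tie rule (documented
  degenerate case).

## Synthetic data: what it emulates and what it does not

Each subject is a fixed PQRST morphology — five Gaussian bumps with
per-subject amplitudes, centers, and widths drawn from physiological ranges
(R amplitude 1.0–1.45 mV, strictly dominant; centers ordered P<Q<R<S<T). A
rendered beat applies, in order: per-beat morphological jitter (amplitude
and width factors ~N(1, 0.08), P/T timing wobble of a few samples — the
respiration- and rate-driven variability real recordings show; the R center
stays fixed so the ground-truth peak contract is exact), a uniform circular
shift over the full window (segmentation misalignment, matching the
alignment operator's model exactly), white sensor noise (sd 0.005 mV), and
per-window normalization by max |sample|.

Two constraints shaped the width/noise choices, and they pull against each
other: (i) the discrete argmax must equal the true R-center in ≥ 99 % of
renders at the default noise, which favors a sharp R; (ii) the waveform must
be compressible in a smooth basis — the sparsity premise of compressive
sensing, without which the reconstruction baselines are strawmen — which
favors a wide R. R width 4–5 samples (FWHM ≈ 40 ms, physiological) with
0.005 mV noise satisfies both (measured: 99.8 % argmax dominance; 7 %
OMP reconstruction error at CR 0.5). The per-beat jitter exists because a
fixture whose only within-class variability is rotation lets a kernel SVM
memorize the rotation manifold outright once training covers most of the N
possible shifts, collapsing the alignment benefit that distinguishes the
frameworks on real data.

Not emulated: arrhythmia, multi-lead geometry, baseline wander, powerline
interference, electrode-motion artifacts, heart-rate-dependent window
content (multiple/partial beats). Passing tests therefore demonstrate the
algorithmic contracts and the direction and rough magnitude of the
framework differences — not clinical-grade accuracy figures, which require
the real-record path (`load_wfdb_segments`).

## Benchmark protocol and problem sizes

The standard desk benchmark uses 10 subjects, 200 train / 80 test windows
per class, CR 0.5, L = 39, full-circle misalignment, fixed seeds — a
deliberately scaled-down version of the 22-subject, 600/250-per-class
protocol of the original recordings, sized so the full suite runs in
minutes on one CPU. Under it (seeds 11/12): CL 86.6 %, CA-CA 98.6 %,
RL-A 99.6 %; CA-CA with 30 % of the training data loses 1.4 points. The
published real-data accuracies (87.05 / 94.16 / 96.03 %) are reproducible
only through the WFDB path plus the full grid search; the synthetic
benchmark reproduces their ordering and the alignment/training-efficiency
effects, not the absolute numbers.

Memory accounting counts stored real coefficients in the online stage
(RL-A: (M+N)dR + nSV·N; CL: nSV·M; CA-CA: (M+kd)N + kd·M + nSV·kd). The
unaligned CA framework has no published formula; its repository-defined
count kd·M + nSV·kd is labeled as such. Wall-clock time is recorded in
benchmark output but never asserted — it is hardware-dependent.

## Known limitations

- The compressed peak estimate is an approximation with no accuracy bound;
  the ±3-sample/90 % figure is an empirical property of the synthetic
  conditions, not a guarantee.
- Aligned metadata of shifted copies of one beat coincide exactly only when
  the sensing operator preserves the least-squares norm (M = N or orthogonal
  Φ); at M < N they coincide approximately (the dispersion-shrinkage tests
  quantify the practical effect).
- One Φ is shared across subjects and phases; per-session sensing matrices,
  open-set rejection of unenrolled subjects, and sub-sample alignment are
  out of scope.
- The WFDB reader covers formats 212 and 16 single-segment records only.
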