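"""Synthetic multi-subject ECG windows for compressed-domain identification studies.

Each subject is a fixed PQRST morphology rendered as a sum of five Gaussian
bumps on a 1-s, 250-sample grid; a recording of that subject is the template
circularly shifted by a random offset (segmentation jitter) plus white sensor
noise, then amplitude-normalized to [-1, 1].  The circular-shift misalignment
model matches the circular-shift alignment operator exactly, so alignment
ground truth is available for every segment.

Peak indices are 1-based throughout the public API, mirroring the usual
matrix-formula convention; ``samples[true_peak_index - 1]`` is the R-peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

N_DEFAULT = 250
SAMPLING_RATE_HZ = 250.0
WAVE_NAMES = ("P", "Q", "R", "S", "T")

# Per-wave (amplitude mV, center sample, width samples) draw ranges.  Centers are
# ordered P < Q < R < S < T by construction; the R amplitude range lies strictly
# above every other wave's so the max-|amplitude| R-peak convention holds.
# Widths keep the waveform compressible in smooth bases (the sparsity premise
# of compressive sensing) while the R bump stays sharp enough that its discrete
# argmax is stable under the default sensor noise.
_WAVE_RANGES = {
    #        amplitude (lo, hi)   center (lo, hi)   width (lo, hi)
    "P": ((0.08, 0.18), (55, 70), (8.0, 12.0)),
    "Q": ((-0.22, -0.10), (112, 116), (3.0, 4.5)),
    "R": ((1.00, 1.45), (124, 126), (4.0, 5.0)),
    "S": ((-0.28, -0.13), (134, 138), (3.0, 4.5)),
    "T": ((0.20, 0.42), (185, 205), (12.0, 18.0)),
}

DEFAULT_NOISE_SD = 0.005  # mV per sample; ~0.5 % of the R amplitude (clean lead)

#: relative sd of per-beat morphological variability (amplitude/width modulation
#: and P/T timing wobble), emulating respiration- and rate-driven beat-to-beat
#: changes; without it every beat of a subject is an exact rotation of one
#: template, which no real recording satisfies.
DEFAULT_BEAT_JITTER = 0.08


@dataclass(frozen=True)
class Wave:
    """One Gaussian bump: ``amplitude * exp(-(n - center)^2 / (2 width^2))``."""

    amplitude: float  # mV
    center: int  # 1-based sample index in [1, N]
    width: float  # samples


@dataclass(frozen=True)
class SubjectTemplate:
    """Fixed PQRST morphology of one subject on an N-sample window."""

    subject_id: int
    waves: tuple[Wave, Wave, Wave, Wave, Wave]  # P, Q, R, S, T order
    baseline_noise_sd: float = DEFAULT_NOISE_SD
    n_samples: int = N_DEFAULT

    def __post_init__(self) -> None:
        amps = [abs(w.amplitude) for w in self.waves]
        if not all(amps[2] > a for i, a in enumerate(amps) if i != 2):
            raise ValueError("R wave must have the strictly largest |amplitude|")
        centers = [w.center for w in self.waves]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ValueError("wave centers must be strictly increasing P<Q<R<S<T")

    @property
    def r_center(self) -> int:
        """1-based sample index of the R-wave center."""
        return self.waves[2].center

    def render(self) -> np.ndarray:
        """Noiseless, unshifted, unnormalized waveform (mV), length N."""
        n = np.arange(1, self.n_samples + 1, dtype=float)
        out = np.zeros(self.n_samples)
        for w in self.waves:
            out += w.amplitude * np.exp(-((n - w.center) ** 2) / (2.0 * w.width**2))
        return out


@dataclass(frozen=True)
class ECGSegment:
    """One amplitude-normalized N-sample ECG window with its subject label.

    ``true_peak_index`` (1-based) is the generator's ground-truth R-peak
    location, or None for segments of unknown provenance (e.g. real records
    before alignment).
    """

    samples: np.ndarray
    subject_id: int
    true_peak_index: int | None = None

    @property
    def n(self) -> int:
        return self.samples.shape[0]


def _normalize(samples: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(samples))
    if peak == 0.0:
        raise ValueError("cannot amplitude-normalize an all-zero segment")
    return samples / peak


def make_subject_template(subject_id: int, rng_seed: int) -> SubjectTemplate:
    """Draw a reproducible per-subject PQRST morphology.

    Distinct seeds give distinct morphologies (continuous draws); the same
    seed reproduces the template bit-for-bit.
    """
    if rng_seed < 0:
        raise ValueError("rng_seed must be a non-negative integer")
    rng = np.random.default_rng(rng_seed)
    waves = []
    for name in WAVE_NAMES:
        (a_lo, a_hi), (c_lo, c_hi), (w_lo, w_hi) = _WAVE_RANGES[name]
        amplitude = float(rng.uniform(a_lo, a_hi))
        center = int(rng.integers(c_lo, c_hi + 1))
        width = float(rng.uniform(w_lo, w_hi))
        waves.append(Wave(amplitude, center, width))
    return SubjectTemplate(subject_id=subject_id, waves=tuple(waves))


def _jittered_waves(
    template: SubjectTemplate, rng: np.random.Generator, beat_jitter: float
) -> tuple[Wave, ...]:
    """Per-beat morphological variation around the subject template.

    Wave amplitudes and widths are modulated by ~N(1, beat_jitter) factors
    (clipped to +-2.5 sd) and the P/T centers wobble by a few samples,
    emulating respiration- and heart-rate-driven beat-to-beat changes.  The
    R center is left untouched: the beat's time reference is randomized by
    the window shift, and the rendered true-peak contract stays exact.
    """
    lo, hi = 1.0 - 2.5 * beat_jitter, 1.0 + 2.5 * beat_jitter
    waves = []
    for name, w in zip(WAVE_NAMES, template.waves):
        amp_scale = float(np.clip(rng.normal(1.0, beat_jitter), lo, hi))
        width_scale = float(np.clip(rng.normal(1.0, 0.5 * beat_jitter), lo, hi))
        center = w.center
        if name in ("P", "T"):
            center = center + int(np.clip(round(rng.normal(0.0, 25 * beat_jitter)), -4, 4))
        waves.append(Wave(w.amplitude * amp_scale, center, w.width * width_scale))
    return tuple(waves)


def render_segment(
    template: SubjectTemplate,
    shift: int,
    noise_sd: float,
    rng_seed: int,
    beat_jitter: float = 0.0,
) -> ECGSegment:
    """Render one noisy, circularly misaligned, normalized window.

    The waveform is the (optionally per-beat jittered) template circularly
    shifted ``shift`` samples (element i moves to (i + shift) mod N) plus
    white Gaussian noise of standard deviation ``noise_sd`` mV, then divided
    by its max |value| so the result lies in [-1, 1] with max |sample|
    exactly 1.  With ``beat_jitter=0`` and ``noise_sd=0`` the output is
    exactly the shifted template rendering.
    """
    n = template.n_samples
    if not 0 <= shift <= n - 1:
        raise ValueError(f"shift must lie in [0, {n - 1}], got {shift}")
    rng = np.random.default_rng(rng_seed)
    if beat_jitter > 0:
        base = replace(
            template, waves=_jittered_waves(template, rng, beat_jitter)
        ).render()
    else:
        base = template.render()
    waveform = np.roll(base, shift)
    if noise_sd > 0:
        waveform = waveform + rng.normal(0.0, noise_sd, n)
    peak = ((template.r_center - 1 + shift) % n) + 1
    return ECGSegment(_normalize(waveform), template.subject_id, peak)


@dataclass
class LabeledDataset:
    """Labeled ECG segments with per-segment train/test split tags."""

    segments: list[ECGSegment]
    splits: list[str]  # "train" | "test", parallel to segments
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.segments)

    def subset(self, split: str) -> "LabeledDataset":
        keep = [i for i, s in enumerate(self.splits) if s == split]
        return LabeledDataset(
            [self.segments[i] for i in keep],
            [split] * len(keep),
            seed=self.seed,
            params=dict(self.params),
        )

    @property
    def train(self) -> "LabeledDataset":
        return self.subset("train")

    @property
    def test(self) -> "LabeledDataset":
        return self.subset("test")

    def signal_matrix(self) -> np.ndarray:
        """N x m matrix whose columns are the segments (the data matrix X)."""
        return np.column_stack([s.samples for s in self.segments])

    def labels(self) -> np.ndarray:
        return np.array([s.subject_id for s in self.segments], dtype=int)

    def subject_ids(self) -> list[int]:
        return sorted({s.subject_id for s in self.segments})

    def limit_train_per_class(self, n_per_class: int) -> "LabeledDataset":
        """Keep only the first ``n_per_class`` training segments of each
        subject; the test split is untouched (paired down-sampling for
        training-size sweeps)."""
        counts: dict[int, int] = {}
        keep = []
        for i, seg in enumerate(self.segments):
            if self.splits[i] != "train":
                keep.append(i)
                continue
            c = counts.get(seg.subject_id, 0)
            if c < n_per_class:
                keep.append(i)
                counts[seg.subject_id] = c + 1
        return LabeledDataset(
            [self.segments[i] for i in keep],
            [self.splits[i] for i in keep],
            seed=self.seed,
            params=dict(self.params),
        )


def generate_dataset(
    n_subjects: int,
    n_train: int,
    n_test: int,
    shift_range: tuple[int, int] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng_seed: int = 0,
    n_samples: int = N_DEFAULT,
    beat_jitter: float = DEFAULT_BEAT_JITTER,
) -> LabeledDataset:
    """Generate a class-balanced multi-subject dataset.

    Per subject, exactly ``n_train`` train and ``n_test`` test segments are
    rendered, each with a shift drawn uniformly from the inclusive
    ``shift_range`` (default: the full circle, (0, N-1)) and independent
    per-beat morphology jitter.  Everything is driven by a single seeded
    generator, so identical arguments reproduce the dataset element-wise.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if n_train <= 0 or n_test <= 0:
        raise ValueError("per-class train/test counts must be positive")
    if shift_range is None:
        shift_range = (0, n_samples - 1)
    lo, hi = shift_range
    if not (0 <= lo <= hi <= n_samples - 1):
        raise ValueError(f"shift_range must satisfy 0 <= lo <= hi <= {n_samples - 1}")

    rng = np.random.default_rng(rng_seed)
    segments: list[ECGSegment] = []
    splits: list[str] = []
    for subject in range(1, n_subjects + 1):
        template_seed = int(rng.integers(0, 2**31))
        template = make_subject_template(subject, template_seed)
        if n_samples != N_DEFAULT:
            template = replace(template, n_samples=n_samples)
        for split, count in (("train", n_train), ("test", n_test)):
            for _ in range(count):
                shift = int(rng.integers(lo, hi + 1))
                seg_seed = int(rng.integers(0, 2**31))
                segments.append(
                    render_segment(template, shift, noise_sd, seg_seed, beat_jitter)
                )
                splits.append(split)
    return LabeledDataset(
        segments,
        splits,
        seed=rng_seed,
        params={
            "n_subjects": n_subjects,
            "n_train": n_train,
            "n_test": n_test,
            "shift_range": list(shift_range),
            "noise_sd": noise_sd,
            "n_samples": n_samples,
            "beat_jitter": beat_jitter,
        },
    )
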