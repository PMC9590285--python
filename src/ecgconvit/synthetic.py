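"""Synthetic ECG beats and analytic test signals.

Every downstream stage of the pipeline (windowing, time-frequency analysis,
oversampling, classification) is exercised on beats produced here, so no
external ECG database is required.  Beats are built from per-class sums of
Gaussian bumps emulating the P/QRS/T morphology of the five AAMI heartbeat
classes (F fusion, N normal, Q unknown/paced, S supraventricular ectopic,
V ventricular ectopic) at the 360 Hz / 300-samples-per-beat convention used
throughout the package.

The morphologies are caricatures, not physiologically validated waveforms:
the R pulse sits at sample 150 (the window centre used by
:mod:`ecgconvit.beats`), class differences are encoded in bump positions,
widths and amplitudes, and the only corruptions modelled are i.i.d. Gaussian
amplitude noise and Gaussian jitter of the bump centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

AAMI_CLASSES = ("F", "N", "Q", "S", "V")

BEAT_LENGTH = 300
SAMPLING_RATE = 360.0


@dataclass(frozen=True)
class BeatTemplate:
    """Gaussian-bump morphology of one AAMI class.

    ``components`` is a sequence of ``(amplitude, center, width)`` triples;
    the waveform is ``sum_k amp_k * exp(-(n - center_k)^2 / (2 width_k^2))``
    evaluated on ``n = 0..299``.
    """

    class_label: str
    components: tuple[tuple[float, float, float], ...]

    def waveform(self, length: int = BEAT_LENGTH,
                 center_shifts: Sequence[float] | None = None) -> np.ndarray:
        n = np.arange(length, dtype=float)
        y = np.zeros(length)
        shifts = center_shifts if center_shifts is not None else [0.0] * len(self.components)
        for (amp, center, width), ds in zip(self.components, shifts):
            y += amp * np.exp(-0.5 * ((n - (center + ds)) / width) ** 2)
        return y


# One template per AAMI class.  R bump at sample 150 in every class; classes
# differ in QRS width, P-wave presence, T-wave polarity and pacing artefacts.
# Pairwise waveform correlations are well below 0.95 (asserted in tests), so
# a nearest-template classifier separates noise-free beats perfectly.
DEFAULT_TEMPLATES: dict[str, BeatTemplate] = {
    "N": BeatTemplate("N", (
        (0.15, 100.0, 8.0),    # P
        (-0.12, 141.0, 3.0),   # Q
        (1.00, 150.0, 4.0),    # R (narrow)
        (-0.22, 159.0, 3.0),   # S
        (0.30, 210.0, 14.0),   # T
    )),
    "V": BeatTemplate("V", (
        (0.95, 150.0, 14.0),   # wide, bizarre QRS, no P
        (-0.35, 178.0, 10.0),
        (-0.40, 225.0, 16.0),  # discordant (inverted) T
    )),
    "S": BeatTemplate("S", (
        (0.22, 120.0, 5.0),    # premature, abnormal P close to QRS
        (0.85, 150.0, 3.0),    # narrow R
        (-0.15, 158.0, 3.0),
        (-0.18, 196.0, 9.0),   # biphasic T
        (0.18, 220.0, 9.0),
    )),
    "F": BeatTemplate("F", (
        (0.08, 105.0, 7.0),    # attenuated P
        (0.65, 150.0, 9.0),    # QRS of intermediate width (fusion of V and N)
        (-0.25, 166.0, 6.0),
        (0.30, 214.0, 15.0),
    )),
    "Q": BeatTemplate("Q", (
        (0.55, 136.0, 1.5),    # pacing spike
        (0.60, 154.0, 10.0),   # wide paced QRS
        (-0.20, 175.0, 6.0),
        (0.22, 230.0, 11.0),   # concordant T (unlike the PVC template)
    )),
}


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Reproducible recipe for a labelled synthetic beat set.

    Parameters
    ----------
    per_class_counts : mapping class label -> number of beats.
    noise_sd : standard deviation of i.i.d. Gaussian amplitude noise.
    jitter_sd : standard deviation (samples) of per-bump centre jitter.
    seed : RNG seed; identical specs generate bitwise-identical datasets.
    """

    per_class_counts: Mapping[str, int]
    noise_sd: float = 0.05
    jitter_sd: float = 0.0
    seed: int = 0
    templates: Mapping[str, BeatTemplate] = field(default_factory=lambda: DEFAULT_TEMPLATES)

    def validate(self) -> None:
        for label, count in self.per_class_counts.items():
            if label not in self.templates:
                raise ValueError(f"unknown class label {label!r}")
            if count < 0:
                raise ValueError(f"negative count for class {label!r}: {count}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.jitter_sd < 0:
            raise ValueError(f"jitter_sd must be >= 0, got {self.jitter_sd}")


def generate_beats(spec: SyntheticDatasetSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate labelled synthetic beats.

    Returns
    -------
    X : float array of shape (n_beats, 300)
    y : object array of AAMI class labels, aligned with ``X`` rows.

    Beats are emitted class by class in sorted label order; shuffle downstream
    if order matters.  ``beat = template(jittered centres) + N(0, noise_sd^2)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows: list[np.ndarray] = []
    labels: list[str] = []
    for label in sorted(spec.per_class_counts):
        template = spec.templates[label]
        count = spec.per_class_counts[label]
        for _ in range(count):
            if spec.jitter_sd > 0:
                shifts = rng.normal(0.0, spec.jitter_sd, size=len(template.components))
            else:
                shifts = np.zeros(len(template.components))
            beat = template.waveform(center_shifts=shifts)
            if spec.noise_sd > 0:
                beat = beat + rng.normal(0.0, spec.noise_sd, size=BEAT_LENGTH)
            rows.append(beat)
            labels.append(label)
    if rows:
        X = np.vstack(rows)
    else:
        X = np.empty((0, BEAT_LENGTH))
    return X, np.array(labels, dtype=object)


def nearest_template_labels(X: np.ndarray,
                            templates: Mapping[str, BeatTemplate] = DEFAULT_TEMPLATES
                            ) -> np.ndarray:
    """Classify beats by Euclidean distance to the class templates."""
    labels = sorted(templates)
    bank = np.vstack([templates[c].waveform() for c in labels])
    d = ((X[:, None, :] - bank[None, :, :]) ** 2).sum(axis=2)
    return np.array([labels[i] for i in d.argmin(axis=1)], dtype=object)


def make_test_signal(kind: str, length: int, params: Mapping | None = None) -> np.ndarray:
    """Analytic test signals used as oracles for the time-frequency code.

    ``kind`` is one of ``impulse`` (unit sample at ``pos``), ``two_impulse``
    (unit samples at ``pos1``/``pos2``), ``sinusoid`` (``freq`` Hz at ``fs``,
    optional ``amplitude``/``phase``), ``chirp`` (linear ``f0``->``f1`` Hz)
    or ``zero``.
    """
    if length <= 0:
        raise ValueError(f"length must be > 0, got {length}")
    p = dict(params or {})
    x = np.zeros(length)
    if kind == "zero":
        return x
    if kind == "impulse":
        pos = int(p["pos"])
        if not 0 <= pos < length:
            raise ValueError(f"impulse position {pos} outside [0, {length})")
        x[pos] = 1.0
        return x
    if kind == "two_impulse":
        for key in ("pos1", "pos2"):
            pos = int(p[key])
            if not 0 <= pos < length:
                raise ValueError(f"impulse position {pos} outside [0, {length})")
            x[pos] += 1.0
        return x
    n = np.arange(length)
    fs = float(p.get("fs", SAMPLING_RATE))
    amp = float(p.get("amplitude", 1.0))
    phase = float(p.get("phase", 0.0))
    if kind == "sinusoid":
        f = float(p["freq"])
        return amp * np.cos(2 * np.pi * f * n / fs + phase)
    if kind == "chirp":
        f0, f1 = float(p["f0"]), float(p["f1"])
        # instantaneous frequency sweeps linearly f0 -> f1 over the signal
        t = n / fs
        duration = length / fs
        return amp * np.cos(2 * np.pi * (f0 * t + (f1 - f0) * t ** 2 / (2 * duration)) + phase)
    raise ValueError(f"unknown test-signal kind {kind!r}")
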