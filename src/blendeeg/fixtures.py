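"""Synthetic EEG cohorts and planted feature benchmarks.

Every downstream stage of the pipeline (feature extraction, selection,
classification, cross-validated grids) is exercised against data produced
here, where the ground truth is known by construction: which frequency
bands carry a class effect, and which feature columns are informative.

The EEG model is deliberately simple resting-state surrogate data: a sum of
band-limited oscillations (random phases, random within-band frequencies)
whose per-band amplitude is scaled by a class-dependent factor, on top of
1/f-shaped broadband noise.  The discriminative signal is therefore a pure
band-power difference between severity classes, which is the kind of
resting-state biomarker the classification pipeline is built to detect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_BANDS",
    "SynthSpec",
    "LabeledEEGSet",
    "EpochSet",
    "FeatureBenchmark",
    "generate_synthetic_cohort",
    "epoch_signals",
    "make_feature_benchmark",
    "save_cohort_csv",
    "load_cohort_csv",
    "save_cohort_edf",
]

#: Conventional clinical EEG bands (Hz).
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


def _default_band_effect() -> list[dict[tuple[float, float], float]]:
    """Per-class band-power factors: a graded alpha-band effect.

    Class 0 (low severity) is the reference; higher severity scales
    alpha-band (8-13 Hz) power up.  All other bands are class-independent.
    """
    alpha = CANONICAL_BANDS["alpha"]
    return [{alpha: 1.0}, {alpha: 1.6}, {alpha: 2.4}]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic resting-state cohort.

    Defaults emulate the structure of a small clinical neuropathic-pain
    cohort: 36 subjects, 3 severity classes, 250 Hz sampling, multichannel
    resting recordings under eyes-open and eyes-closed conditions.
    """

    n_subjects: int = 36
    n_channels: int = 8
    duration_s: float = 60.0
    fs: float = 250.0
    n_classes: int = 3
    band_effect: list[dict[tuple[float, float], float]] = field(
        default_factory=_default_band_effect
    )
    noise_sd: float = 1.0
    osc_amplitude: float = 1.0
    #: relative s.d. of the per-subject multiplicative amplitude jitter
    subject_jitter: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")
        if self.n_subjects < self.n_classes:
            raise ValueError("need at least one subject per class")
        if len(self.band_effect) != self.n_classes:
            raise ValueError(
                f"band_effect has {len(self.band_effect)} entries for "
                f"{self.n_classes} classes"
            )
        nyq = self.fs / 2.0
        for cls_effect in self.band_effect:
            for (lo, hi) in cls_effect:
                if not (0.0 < lo < hi < nyq):
                    raise ValueError(
                        f"band ({lo}, {hi}) Hz must lie inside (0, {nyq}) Hz"
                    )


@dataclass
class LabeledEEGSet:
    """A labelled multi-channel EEG cohort.

    signals has shape (n_subjects, n_channels, n_samples) in microvolt-scaled
    arbitrary units; labels are per-subject severity classes in {0, 1, 2};
    condition tags each subject's segment as eyes-open or eyes-closed.
    """

    signals: np.ndarray
    fs: float
    labels: np.ndarray
    condition: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signals.ndim != 3:
            raise ValueError("signals must be (subject, channel, sample)")
        if len(self.labels) != self.signals.shape[0]:
            raise ValueError("one label per subject required")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")
        if not set(np.unique(self.labels)) <= {0, 1, 2}:
            raise ValueError("labels must be in {0, 1, 2}")

    @property
    def n_subjects(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]


@dataclass
class EpochSet:
    """Fixed-length windows cut from a cohort, labels inherited per subject.

    epochs has shape (n_epochs, n_channels, window_samples).
    """

    epochs: np.ndarray
    fs: float
    labels: np.ndarray
    subject_ids: np.ndarray

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class FeatureBenchmark:
    """A planted-feature classification benchmark with known ground truth."""

    X: np.ndarray
    y: np.ndarray
    informative_idx: np.ndarray

    def __post_init__(self) -> None:
        self.informative_idx = np.asarray(self.informative_idx, dtype=int)
        if self.informative_idx.size and (
            self.informative_idx.min() < 0
            or self.informative_idx.max() >= self.X.shape[1]
        ):
            raise ValueError("informative_idx outside feature range")


def _pink_noise(rng: np.random.Generator, n_samples: int, sd: float) -> np.ndarray:
    """1/f-shaped broadband noise via spectral shaping of white noise."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    # 1/sqrt(f) amplitude shaping gives 1/f power; DC handled separately
    shaping = np.ones_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    shaping[0] = 0.0
    pink = np.fft.irfft(spec * shaping, n=n_samples)
    s = pink.std()
    if s > 0:
        pink *= sd / s
    return pink


def generate_synthetic_cohort(spec: SynthSpec) -> LabeledEEGSet:
    """Simulate a labelled resting-state EEG cohort.

    Each subject's channel signal is a sum over the canonical bands of a
    band-limited oscillation (three random in-band sinusoids with random
    phases) whose amplitude is scaled by sqrt(factor) for the subject's
    class — so band *power* scales by the class factor — plus pink noise.
    Identical specs (including the seed) produce bit-identical cohorts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration_s * spec.fs))
    t = np.arange(n_samples) / spec.fs

    # balanced, deterministic class assignment, then shuffled
    labels = np.arange(spec.n_subjects) % spec.n_classes
    rng.shuffle(labels)
    condition = np.where(
        np.arange(spec.n_subjects) % 2 == 0, "eyes-open", "eyes-closed"
    )
    subject_ids = np.array([f"S{i:03d}" for i in range(spec.n_subjects)])

    # oscillator bands: the canonical set plus any custom bands named in
    # the class effects (deduplicated by interval)
    osc_bands = list(CANONICAL_BANDS.values())
    for cls_effect in spec.band_effect:
        for band in cls_effect:
            if not any(
                abs(band[0] - lo) < 1e-9 and abs(band[1] - hi) < 1e-9
                for lo, hi in osc_bands
            ):
                osc_bands.append(band)

    signals = np.empty((spec.n_subjects, spec.n_channels, n_samples))
    for subj in range(spec.n_subjects):
        cls = labels[subj]
        effect = spec.band_effect[cls]
        jitter = float(
            np.exp(rng.normal(0.0, spec.subject_jitter))
        )  # subject-level amplitude variability
        for ch in range(spec.n_channels):
            sig = np.zeros(n_samples)
            for (lo, hi) in osc_bands:
                factor = 1.0
                for (blo, bhi), f in effect.items():
                    if abs(blo - lo) < 1e-9 and abs(bhi - hi) < 1e-9:
                        factor = f
                amp = spec.osc_amplitude * np.sqrt(factor) * jitter
                for _ in range(3):
                    freq = rng.uniform(lo, hi)
                    phase = rng.uniform(0.0, 2.0 * np.pi)
                    sig += amp * np.sin(2.0 * np.pi * freq * t + phase)
            sig += _pink_noise(rng, n_samples, spec.noise_sd)
            signals[subj, ch] = sig

    return LabeledEEGSet(
        signals=signals,
        fs=spec.fs,
        labels=labels,
        condition=condition,
        subject_ids=subject_ids,
    )


def epoch_signals(
    eeg: LabeledEEGSet, window_s: float = 2.0, overlap_frac: float = 0.0
) -> EpochSet:
    """Cut each recording into fixed-length windows.

    Windows inherit the subject's label and id; trailing partial windows are
    dropped.  A window longer than the recording yields zero epochs for that
    subject and logs a warning.
    """
    if not (0.0 <= overlap_frac < 1.0):
        raise ValueError("overlap_frac must lie in [0, 1)")
    win = int(round(window_s * eeg.fs))
    if win < 2:
        raise ValueError("window must span at least 2 samples")
    stride = max(1, int(round(win * (1.0 - overlap_frac))))
    n_samples = eeg.signals.shape[2]

    epochs, labels, sids = [], [], []
    if n_samples < win:
        warnings.warn(
            f"window of {win} samples exceeds recording length {n_samples}; "
            "no epochs produced",
            stacklevel=2,
        )
    else:
        starts = range(0, n_samples - win + 1, stride)
        for subj in range(eeg.n_subjects):
            for s0 in starts:
                epochs.append(eeg.signals[subj, :, s0 : s0 + win])
                labels.append(eeg.labels[subj])
                sids.append(eeg.subject_ids[subj])
    epochs_arr = (
        np.array(epochs)
        if epochs
        else np.empty((0, eeg.n_channels, win))
    )
    return EpochSet(
        epochs=epochs_arr,
        fs=eeg.fs,
        labels=np.asarray(labels, dtype=int),
        subject_ids=np.asarray(sids, dtype=object),
    )


def make_feature_benchmark(
    n_samples: int = 300,
    n_features: int = 50,
    n_informative: int = 5,
    class_sep: float = 2.0,
    seed: int = 0,
    n_classes: int = 3,
) -> FeatureBenchmark:
    """Planted-feature benchmark: informative columns are class-conditional
    Gaussians whose means are shifted by ``class_sep`` per class step; the
    rest are label-independent standard-normal noise.
    """
    if n_informative > n_features:
        raise ValueError("n_informative cannot exceed n_features")
    if n_samples < 2 * n_classes:
        raise ValueError("need at least 2 samples per class")
    rng = np.random.default_rng(seed)
    y = np.arange(n_samples) % n_classes
    rng.shuffle(y)
    X = rng.standard_normal((n_samples, n_features))
    informative_idx = rng.choice(n_features, size=n_informative, replace=False)
    informative_idx.sort()
    for j in informative_idx:
        # random per-feature class direction so no single feature is trivially
        # ordered the same way as every other
        direction = rng.choice([-1.0, 1.0])
        X[:, j] += direction * class_sep * y
    return FeatureBenchmark(X=X, y=y, informative_idx=informative_idx)


# ---------------------------------------------------------------------------
# writers / readers


def save_cohort_csv(eeg: LabeledEEGSet, out_dir: str | Path) -> Path:
    """Write a cohort as one CSV per subject plus a manifest.

    Each subject file is samples x channels; the manifest records fs,
    labels, conditions and file names.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(eeg.subject_ids):
        fname = f"{sid}.csv"
        df = pd.DataFrame(
            eeg.signals[i].T,
            columns=[f"ch{c}" for c in range(eeg.n_channels)],
        )
        df.to_csv(out / fname, index=False)
        rows.append(
            {
                "subject_id": sid,
                "file": fname,
                "label": int(eeg.labels[i]),
                "condition": str(eeg.condition[i]),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.insert(0, "fs", eeg.fs)
    manifest.to_csv(out / "manifest.csv", index=False)
    return out / "manifest.csv"


def load_cohort_csv(manifest_path: str | Path) -> LabeledEEGSet:
    """Read a cohort written by :func:`save_cohort_csv`."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    fs = float(manifest["fs"].iloc[0])
    signals, labels, conditions, sids = [], [], [], []
    for _, row in manifest.iterrows():
        df = pd.read_csv(manifest_path.parent / row["file"])
        signals.append(df.to_numpy().T)
        labels.append(int(row["label"]))
        conditions.append(str(row["condition"]))
        sids.append(str(row["subject_id"]))
    return LabeledEEGSet(
        signals=np.array(signals),
        fs=fs,
        labels=np.array(labels),
        condition=np.array(conditions),
        subject_ids=np.array(sids),
    )


def save_cohort_edf(eeg: LabeledEEGSet, out_dir: str | Path) -> list[Path]:
    """Export the cohort as one EDF file per subject via MNE.

    Requires mne with EDF-export support; raises a capability error
    otherwise (the CSV writer is the portable path).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise RuntimeError("EDF export requires mne") from exc
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    info = mne.create_info(
        [f"ch{c}" for c in range(eeg.n_channels)], sfreq=eeg.fs, ch_types="eeg"
    )
    paths = []
    for i, sid in enumerate(eeg.subject_ids):
        raw = mne.io.RawArray(eeg.signals[i] * 1e-6, info, verbose="error")
        path = out / f"{sid}.edf"
        try:
            raw.export(str(path), fmt="edf", verbose="error")
        except (ImportError, RuntimeError, ValueError) as exc:
            raise RuntimeError(
                "EDF export unavailable in this installation "
                "(mne export backend missing); use save_cohort_csv"
            ) from exc
        paths.append(path)
    return paths
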