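"""Band-wise EEG features: differential entropy, band power, and the
hemispheric / frontal-posterior asymmetry families derived from them.

The extraction chain mirrors the usual emotion-EEG recipe: resample to
200 Hz, bandpass 0.3-50 Hz, cut 1 s non-overlapping segments, then compute
per-band features for every electrode.

The frontal-posterior family is computed as a plain differential (frontal
minus posterior DE) over the montage's caudal pairs; no causality
estimator is involved despite the historical name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .montage import Montage

__all__ = [
    "BandSet",
    "RawRecording",
    "FeatureTensor",
    "DEFAULT_BANDS",
    "preprocess",
    "segment",
    "de_feature",
    "psd_feature",
    "asymmetry_features",
    "dcau_feature",
    "extract_feature_tensor",
]


@dataclass(frozen=True)
class BandSet:
    """Named frequency bands as (low_hz, high_hz) edges, low to high."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        prev_high = 0.0
        for name, low, high in self.bands:
            if not 0.0 < low < high:
                raise ValueError(f"band {name!r} has invalid edges ({low}, {high})")
            if low < prev_high:
                raise ValueError(f"band {name!r} overlaps its predecessor")
            prev_high = high

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    @property
    def edges(self) -> list[tuple[float, float]]:
        return [(low, high) for _, low, high in self.bands]

    def __len__(self) -> int:
        return len(self.bands)

    def validate_against_fs(self, fs: float) -> None:
        nyq = fs / 2.0
        for name, low, high in self.bands:
            if high >= nyq:
                raise ValueError(
                    f"band {name!r} upper edge {high} Hz is not below Nyquist ({nyq} Hz)"
                )


#: Conventional delta/theta/alpha/beta/gamma edges; overridable everywhere.
DEFAULT_BANDS = BandSet(
    bands=(
        ("delta", 1.0, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 14.0),
        ("beta", 14.0, 31.0),
        ("gamma", 31.0, 50.0),
    )
)


@dataclass
class RawRecording:
    """A multichannel recording: ``signal`` is electrodes x samples in uV."""

    signal: np.ndarray
    fs: float
    label: int | None = None
    subject_id: int | None = None
    trial_id: int | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (electrodes x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.signal).any():
            raise ValueError("signal contains NaNs")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs


@dataclass
class FeatureTensor:
    """Per-segment features: ``values`` is segments x electrodes x bands."""

    values: np.ndarray
    feature_kind: str
    labels: np.ndarray
    subject_ids: np.ndarray
    trial_ids: np.ndarray
    band_names: tuple[str, ...] = field(default=DEFAULT_BANDS.names)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
        self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D (segments x electrodes x bands)")
        n = self.values.shape[0]
        for name in ("labels", "subject_ids", "trial_ids"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} length must equal number of segments ({n})")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def preprocess(
    raw: RawRecording,
    target_fs: float = 200.0,
    passband: tuple[float, float] = (0.3, 50.0),
    filter_order: int = 4,
) -> RawRecording:
    """Resample to ``target_fs`` and zero-phase bandpass to ``passband``.

    Raises if the input sampling rate cannot represent the passband's upper
    edge (``raw.fs < 2 * high``), which would alias.
    """
    low, high = passband
    if raw.fs < 2.0 * high:
        raise ValueError(
            f"sampling rate {raw.fs} Hz is below twice the passband upper edge "
            f"({high} Hz); filtering would alias"
        )
    x = raw.signal
    if raw.fs != target_fs:
        from fractions import Fraction

        frac = Fraction(target_fs / raw.fs).limit_denominator(1000)
        n_out = int(round(x.shape[1] * target_fs / raw.fs))
        x = sps.resample_poly(x, up=frac.numerator, down=frac.denominator, axis=1)
        x = x[:, :n_out]
    sos = sps.butter(filter_order, [low, high], btype="bandpass", fs=target_fs, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=1)
    return RawRecording(
        signal=x,
        fs=target_fs,
        label=raw.label,
        subject_id=raw.subject_id,
        trial_id=raw.trial_id,
    )


def segment(rec: RawRecording, window_s: float = 1.0, overlap_s: float = 0.0) -> list[np.ndarray]:
    """Cut the recording into fixed windows; the trailing remainder is dropped."""
    win = window_s * rec.fs
    if abs(win - round(win)) > 1e-9:
        raise ValueError("window_s x fs must be an integer number of samples")
    win = int(round(win))
    step = int(round((window_s - overlap_s) * rec.fs))
    if step <= 0:
        raise ValueError("overlap must be shorter than the window")
    n = rec.signal.shape[1]
    if n < win:
        import warnings

        warnings.warn("recording shorter than one window; returning no epochs")
        return []
    starts = range(0, n - win + 1, step)
    return [rec.signal[:, s : s + win] for s in starts]


# --------------------------------------------------------------------------
# per-band features
# --------------------------------------------------------------------------

def _band_sos(bands: BandSet, fs: float, order: int) -> list[np.ndarray]:
    return [
        sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
        for low, high in bands.edges
    ]


def de_feature(
    epoch: np.ndarray,
    bands: BandSet = DEFAULT_BANDS,
    fs: float = 200.0,
    filter_order: int = 4,
    on_zero_variance: str = "raise",
) -> np.ndarray:
    """Differential entropy per electrode per band.

    Gaussian closed form ``0.5 * ln(2*pi*e*var)`` of the band-filtered
    signal's time-domain variance. ``on_zero_variance`` is ``"raise"``
    (default) or ``"neginf"``.
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.ndim != 2 or epoch.shape[1] < 2:
        raise ValueError("epoch must be electrodes x samples with >= 2 samples")
    bands.validate_against_fs(fs)
    out = np.empty((epoch.shape[0], len(bands)))
    for j, sos in enumerate(_band_sos(bands, fs, filter_order)):
        filtered = sps.sosfiltfilt(sos, epoch, axis=1)
        var = filtered.var(axis=1)
        zero = var <= 0
        if zero.any():
            if on_zero_variance == "raise":
                raise ValueError(
                    f"zero variance in band {bands.names[j]!r} for electrodes "
                    f"{np.flatnonzero(zero).tolist()}"
                )
            out[:, j] = np.where(zero, -np.inf, 0.5 * np.log(2 * np.pi * np.e * np.where(zero, 1, var)))
            continue
        out[:, j] = 0.5 * np.log(2 * np.pi * np.e * var)
    return out


def psd_feature(
    epoch: np.ndarray,
    bands: BandSet = DEFAULT_BANDS,
    fs: float = 200.0,
) -> np.ndarray:
    """Band power per electrode: the Hann-windowed averaged periodogram
    integrated over each band's frequency range (units uV^2).

    On a 1 s epoch the averaged periodogram collapses to a single windowed
    periodogram.
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.ndim != 2:
        raise ValueError("epoch must be electrodes x samples")
    bands.validate_against_fs(fs)
    nperseg = min(epoch.shape[1], int(fs))
    freqs, pxx = sps.welch(epoch, fs=fs, window="hann", nperseg=nperseg, axis=1)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    out = np.empty((epoch.shape[0], len(bands)))
    for j, (low, high) in enumerate(bands.edges):
        mask = (freqs >= low) & (freqs < high)
        out[:, j] = pxx[:, mask].sum(axis=1) * df
    return out


def asymmetry_features(
    de: np.ndarray,
    montage: Montage,
    kind: str,
    rasm_guard: float = 1e-8,
    clip_rasm: bool = False,
) -> np.ndarray:
    """Left-right asymmetry rows over the montage's mirror pairs.

    ``kind="DASM"`` takes left minus right; ``kind="RASM"`` left over
    right. Near-zero RASM denominators raise unless ``clip_rasm`` is set,
    in which case they are clipped to ``+-rasm_guard``.
    """
    de = np.asarray(de, dtype=np.float64)
    if de.shape[0] != montage.n_electrodes:
        raise ValueError(
            f"feature matrix has {de.shape[0]} electrodes, montage has {montage.n_electrodes}"
        )
    left = np.array([a for a, _ in montage.mirror_pairs])
    right = np.array([b for _, b in montage.mirror_pairs])
    kind = kind.upper()
    if kind == "DASM":
        return de[left] - de[right]
    if kind == "RASM":
        denom = de[right]
        small = np.abs(denom) < rasm_guard
        if small.any():
            if not clip_rasm:
                raise ValueError(
                    f"RASM denominator below {rasm_guard} at {int(small.sum())} entries"
                )
            denom = np.where(small, np.sign(denom) * rasm_guard + (denom == 0) * rasm_guard, denom)
        return de[left] / denom
    raise ValueError(f"unknown asymmetry kind {kind!r}")


def dcau_feature(de: np.ndarray, montage: Montage) -> np.ndarray:
    """Frontal-minus-posterior differential over the montage's caudal pairs."""
    de = np.asarray(de, dtype=np.float64)
    if not montage.caudal_pairs:
        raise ValueError("montage has no caudal pairs; cannot compute frontal-posterior features")
    if de.shape[0] != montage.n_electrodes:
        raise ValueError(
            f"feature matrix has {de.shape[0]} electrodes, montage has {montage.n_electrodes}"
        )
    front = np.array([a for a, _ in montage.caudal_pairs])
    back = np.array([b for _, b in montage.caudal_pairs])
    return de[front] - de[back]


# --------------------------------------------------------------------------
# end-to-end convenience
# --------------------------------------------------------------------------

_BASE_KINDS = {"DE": de_feature, "PSD": psd_feature}


def extract_feature_tensor(
    recordings: list[RawRecording],
    montage: Montage,
    feature_kind: str = "DE",
    bands: BandSet = DEFAULT_BANDS,
    target_fs: float = 200.0,
    passband: tuple[float, float] = (0.3, 50.0),
    window_s: float = 1.0,
    asymmetry_base: str = "DE",
) -> FeatureTensor:
    """Run preprocess -> segment -> per-band features over whole recordings.

    Asymmetry families (DASM/RASM/DCAU) are derived per segment from the
    ``asymmetry_base`` feature (DE by default).
    """
    feature_kind = feature_kind.upper()
    values, labels, subjects, trials = [], [], [], []
    for rec in recordings:
        if rec.n_channels != montage.n_electrodes:
            raise ValueError(
                f"recording has {rec.n_channels} channels, montage expects {montage.n_electrodes}"
            )
        clean = preprocess(rec, target_fs=target_fs, passband=passband)
        for epoch in segment(clean, window_s=window_s):
            if feature_kind in _BASE_KINDS:
                feats = _BASE_KINDS[feature_kind](epoch, bands, clean.fs)
            else:
                base = _BASE_KINDS[asymmetry_base.upper()](epoch, bands, clean.fs)
                if feature_kind in ("DASM", "RASM"):
                    feats = asymmetry_features(base, montage, kind=feature_kind)
                elif feature_kind == "DCAU":
                    feats = dcau_feature(base, montage)
                else:
                    raise ValueError(f"unknown feature kind {feature_kind!r}")
            values.append(feats)
            labels.append(-1 if rec.label is None else rec.label)
            subjects.append(-1 if rec.subject_id is None else rec.subject_id)
            trials.append(-1 if rec.trial_id is None else rec.trial_id)
    return FeatureTensor(
        values=np.stack(values),
        feature_kind=feature_kind,
        labels=np.array(labels),
        subject_ids=np.array(subjects),
        trial_ids=np.array(trials),
        band_names=bands.names,
    )
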