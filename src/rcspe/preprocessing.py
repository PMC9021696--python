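"""Modality-specific preprocessing: filtering, resampling, epoching,
baseline correction, z-scoring, Beer-Lambert conversion, channel selection.

The EEG chain is: common-average re-reference -> 0.5-50 Hz band-pass ->
down-sample to 200 Hz -> 8-30 Hz band-pass -> z-score -> epoch -3..7 s ->
baseline-correct on -3..0 s, restricted to the eight motor-cortex electrodes.
The fNIRS chain is: 0.01-0.1 Hz band-pass -> modified Beer-Lambert conversion
to HbO/HbR -> epoch 0..10 s -> baseline-correct on 0..3 s, on the channels
near the motor cortex.

All filters are zero-phase Butterworth (applied forward-backward), order 4
for the EEG bands and order 3 for the very low fNIRS band where higher orders
are numerically fragile.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import EpochWindow, TrialSet
from .errors import DegenerateInputError, InvalidInputError

EEG_MOTOR_CHANNELS = [
    "FCC5h", "FCC6h", "FCC3h", "FCC4h", "CCP5h", "CCP6h", "CCP3h", "CCP4h",
]

EEG_WIDE_BAND = (0.5, 50.0)
EEG_MI_BAND = (8.0, 30.0)
FNIRS_BAND = (0.01, 0.1)
EEG_EPOCH = EpochWindow(-3.0, 7.0)
FNIRS_EPOCH = EpochWindow(0.0, 10.0)
EEG_BASELINE = EpochWindow(-3.0, 0.0)
FNIRS_BASELINE = EpochWindow(0.0, 3.0)

#: Molar extinction coefficients [cm^-1 / (mol/L)] of HbO and HbR at common
#: fNIRS wavelengths (standard compiled spectra).
EXTINCTION_COEFFICIENTS: dict[float, tuple[float, float]] = {
    690.0: (276.0, 2051.96),
    760.0: (1486.59, 3843.71),
    780.0: (735.0, 1075.0),
    830.0: (974.0, 693.04),
    850.0: (2526.39, 1798.64),
}


def _apply_zero_phase(data: np.ndarray, sos: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, data, axis=-1)


def bandpass_filter(trials: TrialSet, low: float, high: float, order: int = 4) -> TrialSet:
    """Zero-phase Butterworth band-pass along the sample axis."""
    nyq = trials.fs / 2.0
    if not 0 < low < high < nyq:
        raise InvalidInputError(
            f"band [{low}, {high}] Hz invalid for fs={trials.fs} Hz (Nyquist {nyq})"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=trials.fs, output="sos")
    return trials.with_data(_apply_zero_phase(trials.data, sos))


def resample(trials: TrialSet, target_fs: float) -> TrialSet:
    """Anti-aliased down-sampling (polyphase) to ``target_fs``."""
    if target_fs > trials.fs:
        raise InvalidInputError(
            f"upsampling unsupported: target {target_fs} Hz > fs {trials.fs} Hz"
        )
    if target_fs == trials.fs:
        return trials.with_data(trials.data.copy())
    frac = Fraction(target_fs / trials.fs).limit_denominator(1000)
    out = signal.resample_poly(trials.data, frac.numerator, frac.denominator, axis=-1)
    return trials.with_data(out, fs=target_fs)


def epoch(
    continuous: np.ndarray,
    event_times: np.ndarray,
    window: EpochWindow,
    fs: float,
    channel_names: list[str] | None = None,
    labels: np.ndarray | None = None,
) -> TrialSet:
    """Cut a continuous recording ``(channels, samples)`` into cue-locked epochs.

    Each epoch covers ``[event + window.start, event + window.end)`` and has
    ``round(window.length * fs)`` samples; its ``t0`` equals ``window.start``.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    event_times = np.asarray(event_times, dtype=float)
    n_ch, n_total = continuous.shape
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_ch)]
    n_samp = int(round(window.length * fs))
    epochs = np.empty((event_times.size, n_ch, n_samp))
    for i, ev in enumerate(event_times):
        start = int(round((ev + window.start) * fs))
        if start < 0 or start + n_samp > n_total:
            raise IndexError(
                f"trial {i}: window [{ev + window.start}, {ev + window.end}) s "
                f"outside recording of {n_total / fs} s"
            )
        epochs[i] = continuous[:, start:start + n_samp]
    return TrialSet(epochs, fs, channel_names, t0=window.start, labels=labels)


def baseline_correct(trials: TrialSet, window: EpochWindow) -> TrialSet:
    """Subtract the per-trial, per-channel mean of ``window`` from every sample."""
    sl = trials.sample_slice(window)
    if sl.stop <= sl.start:
        raise InvalidInputError("baseline window contains no samples")
    baseline = trials.data[:, :, sl].mean(axis=-1, keepdims=True)
    return trials.with_data(trials.data - baseline)


def zscore_normalize(trials: TrialSet) -> TrialSet:
    """Per-trial, per-channel z-score using the population SD (divide by n)."""
    mean = trials.data.mean(axis=-1, keepdims=True)
    sd = trials.data.std(axis=-1, keepdims=True)
    tiny = 1e-12 * np.maximum(np.abs(mean), 1.0)
    flat = np.nonzero((sd <= tiny).squeeze(-1))
    if flat[0].size:
        tr, ch = flat[0][0], flat[1][0]
        raise DegenerateInputError(
            f"zero-variance channel '{trials.channel_names[ch]}' in trial {tr}"
        )
    return trials.with_data((trials.data - mean) / sd)


def common_average_reference(trials: TrialSet) -> TrialSet:
    """Re-reference each sample to the mean over channels."""
    return trials.with_data(trials.data - trials.data.mean(axis=1, keepdims=True))


def select_channels(trials: TrialSet, names: list[str]) -> TrialSet:
    """Restrict and reorder channels to ``names`` (exact order)."""
    missing = [n for n in names if n not in trials.channel_names]
    if missing:
        raise KeyError(f"unknown channel name(s): {missing}")
    idx = [trials.channel_names.index(n) for n in names]
    return trials.with_data(trials.data[:, idx, :].copy(), channel_names=list(names))


@dataclass
class OpticalRecording:
    """Raw dual-wavelength optical intensities ``(channels, samples, 2)``.

    ``source_detector_distance`` is in cm; ``wavelengths`` in nm must be two
    distinct keys of :data:`EXTINCTION_COEFFICIENTS` (or supplied coefficients).
    """

    intensity: np.ndarray
    fs: float
    source_detector_distance: float = 3.0
    wavelengths: tuple[float, float] = (760.0, 850.0)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[-1] != 2:
            raise InvalidInputError(
                "intensity must have shape (channels, samples, 2 wavelengths)"
            )
        if np.any(self.intensity <= 0):
            raise InvalidInputError("optical intensities must be strictly positive")
        if self.wavelengths[0] == self.wavelengths[1]:
            raise InvalidInputError("the two wavelengths must be distinct")
        if self.source_detector_distance <= 0:
            raise InvalidInputError("source-detector distance must be positive")


def extinction_matrix(wavelengths: tuple[float, float]) -> np.ndarray:
    """2x2 matrix of molar extinction coefficients, rows = wavelengths,
    columns = (HbO, HbR)."""
    try:
        rows = [EXTINCTION_COEFFICIENTS[w] for w in wavelengths]
    except KeyError as exc:  # pragma: no cover - guarded by callers
        raise InvalidInputError(
            f"no extinction coefficients tabulated for {exc.args[0]} nm"
        ) from None
    return np.asarray(rows, dtype=float)


def mbll_convert(
    rec: OpticalRecording,
    dpf: tuple[float, float] = (6.0, 6.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Modified Beer-Lambert conversion of intensities to (dHbO, dHbR) in uM.

    Optical-density change per wavelength is ``dOD = -log10(I / I0)`` with
    ``I0`` the channel's temporal mean intensity.  Per sample the 2x2 system
    ``E @ c = dOD / (d * DPF)`` is solved by least squares, giving molar
    concentration changes that are returned in micromolar.
    """
    if dpf[0] <= 0 or dpf[1] <= 0:
        raise InvalidInputError("differential pathlength factors must be positive")
    ext = extinction_matrix(rec.wavelengths)
    if abs(np.linalg.det(ext)) < 1e-12:
        raise InvalidInputError("extinction matrix is singular")
    i0 = rec.intensity.mean(axis=1, keepdims=True)
    dod = -np.log10(rec.intensity / i0)  # (ch, samp, 2)
    rhs = dod / (rec.source_detector_distance * np.asarray(dpf))
    # solve E c = rhs for every (channel, sample)
    conc = np.linalg.solve(ext[None, None, :, :], rhs[..., None]).squeeze(-1)
    hbo = conc[..., 0] * 1e6
    hbr = conc[..., 1] * 1e6
    return hbo, hbr


def remove_ocular_artifacts(
    trials: TrialSet,
    frontal_channels: tuple[str, str],
    threshold: float = 0.7,
    seed: int = 0,
) -> TrialSet:
    """ICA-based ocular-artifact rejection.

    Decomposes the concatenated trials with FastICA, zeroes every component
    whose absolute correlation with either designated frontal channel exceeds
    ``threshold``, and remixes.  Frontal channels serve as an EOG surrogate.
    """
    from sklearn.decomposition import FastICA

    for name in frontal_channels:
        if name not in trials.channel_names:
            raise KeyError(f"unknown frontal channel '{name}'")
    n_tr, n_ch, n_samp = trials.data.shape
    concat = trials.data.transpose(1, 0, 2).reshape(n_ch, -1)
    ica = FastICA(
        n_components=n_ch, whiten="unit-variance", fun="logcosh",
        max_iter=500, tol=1e-4, random_state=seed,
    )
    sources = ica.fit_transform(concat.T).T  # (comp, samples)
    keep = np.ones(n_ch, dtype=bool)
    for name in frontal_channels:
        ref = concat[trials.channel_names.index(name)]
        for j in range(n_ch):
            r = np.corrcoef(sources[j], ref)[0, 1]
            if abs(r) > threshold:
                keep[j] = False
    cleaned = ica.mixing_ @ (sources * keep[:, None]) + ica.mean_[:, None]
    return trials.with_data(cleaned.reshape(n_ch, n_tr, n_samp).transpose(1, 0, 2))


def preprocess_eeg(
    trials: TrialSet,
    channels: list[str] | None = None,
    baseline: EpochWindow = EEG_BASELINE,
) -> TrialSet:
    """Epoch-level EEG chain on already-epoched trials:
    re-reference -> 8-30 Hz -> z-score -> baseline-correct -> channel subset."""
    out = common_average_reference(trials)
    out = bandpass_filter(out, *EEG_MI_BAND, order=4)
    out = zscore_normalize(out)
    out = baseline_correct(out, baseline)
    if channels:
        out = select_channels(out, channels)
    return out


def preprocess_fnirs(
    trials: TrialSet,
    channels: list[str] | None = None,
    baseline: EpochWindow = FNIRS_BASELINE,
) -> TrialSet:
    """Epoch-level fNIRS chain on already-epoched concentration trials:
    baseline-correct 0-3 s -> channel subset.

    Band-pass filtering and Beer-Lambert conversion act on the continuous
    recording before epoching; see :func:`bandpass_filter` and
    :func:`mbll_convert`.
    """
    out = baseline_correct(trials, baseline)
    if channels:
        out = select_channels(out, channels)
    return out
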