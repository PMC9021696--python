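"""Synthetic paired EEG/fNIRS motor-imagery sessions with known ground truth.

The generator emulates the statistical structure of a simultaneously recorded
two-class motor-imagery session: a small set of latent cortical sources is
mixed into both modalities.  In EEG the two discriminative sources are 8-30 Hz
band-limited oscillations whose task-window variance is modulated
contralaterally by the class (event-related desynchronisation); in fNIRS the
same source identities carry a class-lateralised, HRF-shaped HbO response.
The two modalities use different (independently drawn, localized) channel
weightings of the same sources, so only the *identity* of the active sources
is shared — which is exactly the assumption the cross-modal transfer method
relies on.

Every session records its ground-truth mixing matrices, so component-selection
and channel-ranking steps can be validated against the latent truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gamma as gamma_dist

from .containers import GroundTruth, MultimodalSession, TrialSet
from .errors import InvalidInputError

_EEG_MOTOR_CHANNELS = [
    "FCC5h", "FCC6h", "FCC3h", "FCC4h", "CCP5h", "CCP6h", "CCP3h", "CCP4h",
]

#: Fraction of HbO signal mirrored (with opposite sign) into HbR.
HBR_RATIO = -0.3


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated paired session.

    Defaults emulate a single subject of the public hybrid motor-imagery
    protocol the method targets: 60 trials (30 per class), 8 motor-cortex EEG
    channels at 200 Hz spanning -3..7 s around the cue, 24 fNIRS channels at
    12.5 Hz spanning the 0..10 s task period.
    """

    n_trials_per_class: int = 30
    n_eeg_channels: int = 8
    n_fnirs_channels: int = 24
    fs_eeg: float = 200.0
    fs_fnirs: float = 12.5
    trial_len_eeg: float = 10.0
    trial_len_fnirs: float = 10.0
    t0_eeg: float = -3.0
    t0_fnirs: float = 0.0
    n_sources: int = 4
    n_discriminative: int = 2
    erd_depth: float = 0.6
    hrf_amplitude: float = 1.0
    hrf_lateralization: float = 1.0
    hrf_gain_jitter: float = 0.5
    hrf_source_noise: float = 0.3
    snr_eeg: float = 5.0
    snr_fnirs: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_class < 2:
            raise InvalidInputError("need at least 2 trials per class")
        if self.n_eeg_channels < 2 or self.n_fnirs_channels < 2:
            raise InvalidInputError("need at least 2 channels per modality")
        if self.n_sources < 2 or self.n_sources > min(
            self.n_eeg_channels, self.n_fnirs_channels
        ):
            raise InvalidInputError(
                "n_sources must be in [2, min(channel counts)]"
            )
        if not 0 <= self.n_discriminative <= self.n_sources:
            raise InvalidInputError("n_discriminative must be <= n_sources")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise InvalidInputError("erd_depth must lie in [0, 1]")
        if not 0.0 <= self.hrf_lateralization <= 1.0:
            raise InvalidInputError("hrf_lateralization must lie in [0, 1]")
        if self.hrf_gain_jitter < 0 or self.hrf_source_noise < 0:
            raise InvalidInputError("HRF variability parameters must be >= 0")
        if self.snr_eeg <= 0 or self.snr_fnirs <= 0:
            raise InvalidInputError("SNRs must be positive (np.inf allowed)")


def canonical_hrf(
    t_grid: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, scaled to unit peak.

    ``h(t) = g(t; peak_delay) - undershoot_ratio * g(t; undershoot_delay)``
    with ``g`` a gamma density of unit scale, so the response is 0 at t = 0,
    peaks near ``peak_delay`` seconds and (for a positive ratio) undershoots
    around ``undershoot_delay`` seconds before decaying back to zero.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InvalidInputError("t_grid must be a non-empty 1-D array")
    if t[0] != 0 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise InvalidInputError("t_grid must start at 0 and be strictly ascending")
    # unit-scale gamma density peaks at (a - 1), so shape = delay + 1
    h = gamma_dist.pdf(t, a=peak_delay + 1.0, scale=1.0)
    h = h - undershoot_ratio * gamma_dist.pdf(t, a=undershoot_delay + 1.0, scale=1.0)
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def make_mixing(
    n_channels: int, n_sources: int, smoothness: float, seed: int
) -> np.ndarray:
    """Random localized topographies: unit-norm, full-rank mixing columns.

    Each source projects as a non-negative Gaussian bump over the channel
    axis — the sensitivity profile of a compact cortical patch seen by a
    nearby sensor array (optical channels weight a concentration source
    non-negatively; over a small electrode patch the EEG magnitude topography
    of one source is likewise single-signed).  Bump centres are spread along
    the channel axis with random jitter, amplitudes are multiplicatively
    perturbed.  ``smoothness`` sets the bump width in channel-index units
    (<= 0 falls back to unstructured non-negative weights).  Deterministic
    per seed.
    """
    if n_sources > n_channels:
        raise InvalidInputError(
            f"n_sources ({n_sources}) exceeds n_channels ({n_channels})"
        )
    rng = np.random.default_rng(seed)
    idx = np.arange(n_channels, dtype=float)
    for _ in range(16):
        if smoothness > 0:
            base = np.linspace(0, n_channels - 1, n_sources + 2)[1:-1]
            spacing = n_channels / (n_sources + 1)
            centers = rng.permutation(base) + rng.uniform(
                -0.3, 0.3, n_sources
            ) * spacing
            a = np.exp(
                -0.5 * ((idx[:, None] - centers[None, :]) / smoothness) ** 2
            )
            a = a * (1.0 + 0.2 * rng.standard_normal(a.shape))
        else:
            a = rng.standard_normal((n_channels, n_sources))
        a = np.abs(a) + 1e-3
        a = a / np.linalg.norm(a, axis=0, keepdims=True)
        if np.linalg.matrix_rank(a, tol=1e-8) == n_sources:
            return a
    raise InvalidInputError("could not draw a full-rank mixing matrix")  # pragma: no cover


def _band_limited_noise(
    rng: np.random.Generator, n_samples: int, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [low, high] Hz."""
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    # pad so the filter transient does not bias the trial
    pad = int(fs)
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples + 2 * pad))[pad:-pad]
    return x / x.std()


def _bursty_oscillation(
    rng: np.random.Generator, n_samples: int, fs: float, env_depth: float = 0.3
) -> np.ndarray:
    """8-30 Hz oscillation with a slowly varying amplitude envelope.

    Cortical rhythms wax and wane in bursts; the log-normal envelope makes
    the source super-Gaussian, which is also what renders it identifiable to
    ICA (a stationary band-limited Gaussian process is not).
    """
    x = _band_limited_noise(rng, n_samples, fs, 8.0, 30.0)
    if env_depth > 0:
        env = gaussian_filter1d(rng.standard_normal(n_samples), sigma=0.5 * fs)
        env = np.exp(env_depth * env / max(env.std(), 1e-12))
        x = x * env
        x = x / x.std()
    return x


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float) -> np.ndarray:
    """1/f-spectrum noise, unit variance along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    envelope = np.ones_like(freqs)
    nz = freqs > 0
    envelope[nz] = 1.0 / np.sqrt(freqs[nz])
    envelope[0] = 0.0  # no DC
    pink = np.fft.irfft(spec * envelope, n=n, axis=-1)
    return pink / pink.std(axis=-1, keepdims=True)


def _scaled_noise_power(sig: np.ndarray, snr: float) -> float:
    """Noise variance target so that signal power / noise power == snr."""
    if np.isinf(snr):
        return 0.0
    return float(np.mean(sig**2)) / snr


def _eeg_trials(cfg: SimConfig, labels: np.ndarray, mixing: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    n_samp = int(round(cfg.trial_len_eeg * cfg.fs_eeg))
    times = cfg.t0_eeg + np.arange(n_samp) / cfg.fs_eeg
    task = times >= 0.0
    data = np.empty((labels.size, cfg.n_eeg_channels, n_samp))
    for i, lab in enumerate(labels):
        sources = np.empty((cfg.n_sources, n_samp))
        for j in range(cfg.n_sources):
            s = _bursty_oscillation(rng, n_samp, cfg.fs_eeg)
            if j < cfg.n_discriminative:
                # contralateral ERD: source 0 suppressed for left, source 1 for right
                sign = -1.0 if (j % 2 == 0) == (lab == 1) else 1.0
                scale = np.sqrt(max(1.0 + sign * cfg.erd_depth, 0.0))
                s = np.where(task, s * scale, s)
            sources[j] = s
        clean = mixing @ sources
        noise_var = _scaled_noise_power(clean, cfg.snr_eeg)
        if noise_var > 0:
            clean = clean + np.sqrt(noise_var) * _pink_noise(
                rng, (cfg.n_eeg_channels, n_samp), cfg.fs_eeg
            )
        data[i] = clean
    return data


def _fnirs_trials(cfg: SimConfig, labels: np.ndarray, mixing: np.ndarray,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n_samp = int(round(cfg.trial_len_fnirs * cfg.fs_fnirs))
    t = np.arange(n_samp) / cfg.fs_fnirs
    hrf = canonical_hrf(t)
    boxcar = np.ones(n_samp)
    resp = np.convolve(boxcar, hrf)[:n_samp]
    peak = resp.max()
    if peak > 0:
        resp = resp / peak  # unit-peak task response within the trial

    hbo = np.empty((labels.size, cfg.n_fnirs_channels, n_samp))
    hbr = np.empty_like(hbo)
    for i, lab in enumerate(labels):
        sources = np.zeros((cfg.n_sources, n_samp))
        for j in range(cfg.n_discriminative):
            sign = -1.0 if (j % 2 == 0) == (lab == 1) else 1.0
            amp = cfg.hrf_amplitude * (1.0 + sign * cfg.hrf_lateralization)
            # per-trial gain jitter and source-specific slow fluctuation:
            # physiological variability that also makes the haemodynamic
            # sources mutually independent (identifiable by ICA) instead of
            # exact scalar multiples of one HRF curve
            gain = max(1.0 + cfg.hrf_gain_jitter * rng.standard_normal(), 0.2)
            slow = gaussian_filter1d(rng.standard_normal(n_samp), sigma=cfg.fs_fnirs)
            slow = slow / max(slow.std(), 1e-12)
            sources[j] = amp * resp * gain + cfg.hrf_source_noise * cfg.hrf_amplitude * slow
        # non-discriminative sources: weak slow background fluctuation
        for j in range(cfg.n_discriminative, cfg.n_sources):
            drift = rng.standard_normal(3)
            sources[j] = 0.2 * cfg.hrf_amplitude * (
                drift[0] * np.sin(2 * np.pi * 0.05 * t + drift[1]) + drift[2] * t / t[-1]
            )
        clean = mixing @ sources
        noise_var = _scaled_noise_power(clean, cfg.snr_fnirs)
        if noise_var > 0:
            amp = np.sqrt(noise_var)
            # after the 0.01-0.1 Hz band-pass of the preprocessing chain,
            # real fNIRS noise is dominated by slow physiology; broadband
            # measurement noise is a minor component.  Slow noise has few
            # effective degrees of freedom per 10 s trial, which is what
            # makes fNIRS covariance and mean-amplitude estimates so much
            # poorer than EEG ones.  Each channel's slow noise is
            # independent (channel-local haemodynamics), the Mayer-wave
            # frequency jitters per channel, and only a small linear drift
            # survives the band-pass.
            freq = 0.1 * (1.0 + 0.1 * rng.standard_normal((cfg.n_fnirs_channels, 1)))
            mayer = np.sin(
                2 * np.pi * freq * t[None, :]
                + rng.uniform(0, 2 * np.pi, (cfg.n_fnirs_channels, 1))
            )
            slow = gaussian_filter1d(
                rng.standard_normal((cfg.n_fnirs_channels, n_samp)),
                sigma=1.5 * cfg.fs_fnirs, axis=-1,
            )
            slow = slow / np.maximum(slow.std(axis=-1, keepdims=True), 1e-12)
            slope = rng.standard_normal((cfg.n_fnirs_channels, 1))
            drift = slope * (t[None, :] / t[-1])  # uncentred: trial means drift
            white = rng.standard_normal((cfg.n_fnirs_channels, n_samp))
            noise = 1.0 * slow + 0.6 * mayer + 0.6 * drift + 0.3 * white
            noise = noise / noise.std(axis=-1, keepdims=True)
            hbo_noise = amp * noise
        else:
            hbo_noise = 0.0
        hbo[i] = clean + hbo_noise
        if noise_var > 0:
            hbr_noise = np.sqrt(noise_var) * abs(HBR_RATIO) * rng.standard_normal(
                (cfg.n_fnirs_channels, n_samp)
            )
        else:
            hbr_noise = 0.0
        hbr[i] = HBR_RATIO * clean + hbr_noise
    return hbo, hbr


def generate_session(config: SimConfig) -> MultimodalSession:
    """Generate one paired two-class session with balanced, shuffled labels."""
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    s_labels, s_mix_eeg, s_mix_fnirs, s_eeg, s_fnirs = root.spawn(5)

    n_trials = 2 * cfg.n_trials_per_class
    labels = np.repeat([1, 2], cfg.n_trials_per_class)
    labels = np.random.default_rng(s_labels).permutation(labels)

    mixing_eeg = make_mixing(
        cfg.n_eeg_channels, cfg.n_sources, smoothness=1.0,
        seed=int(s_mix_eeg.generate_state(1)[0] % (2**31)),
    )
    mixing_fnirs = make_mixing(
        cfg.n_fnirs_channels, cfg.n_sources, smoothness=2.0,
        seed=int(s_mix_fnirs.generate_state(1)[0] % (2**31)),
    )

    eeg_data = _eeg_trials(cfg, labels, mixing_eeg, np.random.default_rng(s_eeg))
    hbo_data, hbr_data = _fnirs_trials(
        cfg, labels, mixing_fnirs, np.random.default_rng(s_fnirs)
    )

    if cfg.n_eeg_channels == len(_EEG_MOTOR_CHANNELS):
        eeg_names = list(_EEG_MOTOR_CHANNELS)
    else:
        eeg_names = [f"EEG{i + 1}" for i in range(cfg.n_eeg_channels)]
    fnirs_names = [f"CH{i + 1}" for i in range(cfg.n_fnirs_channels)]

    eeg = TrialSet(eeg_data, cfg.fs_eeg, eeg_names, t0=cfg.t0_eeg, labels=labels)
    hbo = TrialSet(hbo_data, cfg.fs_fnirs, fnirs_names, t0=cfg.t0_fnirs, labels=labels)
    hbr = TrialSet(
        hbr_data, cfg.fs_fnirs, list(fnirs_names), t0=cfg.t0_fnirs, labels=labels
    )
    truth = GroundTruth(
        mixing_eeg=mixing_eeg,
        mixing_fnirs=mixing_fnirs,
        discriminative_sources=np.arange(cfg.n_discriminative),
    )
    assert labels.size == n_trials
    return MultimodalSession(eeg=eeg, fnirs_hbo=hbo, fnirs_hbr=hbr,
                             labels=labels, truth=truth)
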