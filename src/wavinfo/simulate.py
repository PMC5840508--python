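"""Synthetic evoked-potential benchmark generator.

Emulates a four-class single-channel ERP experiment: each class is defined by
one or two Gaussian-shaped components (amplitude, latency, width), every trial
jitters all components together by a uniform draw (default +/-5 ms), and the
clean pattern is buried in spectrally realistic background noise (1/f
amplitude spectrum plus an alpha bump at 10 Hz) rescaled per trial so that the
clean-pattern power over noise power equals the requested SNR (default 0.33,
i.e. noise power three times the pattern power). Default geometry: 500 ms
epochs at 256 Hz (128 samples, dyadic) and 100 trials per class.

The four default class waveforms make peak amplitude and latency deliberately
uninformative for two class pairs: classes 1 and 2 share peak amplitude and
latency and differ only in width (shape), class 3 and the two-component
class 4 have slightly smaller amplitudes and later latencies. Peak-feature
decoders can therefore separate {1,2} from {3,4} but not within the pairs,
while the full waveform shape separates all four.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import TrialSet

__all__ = [
    "WaveformSpec",
    "NoiseSpec",
    "SimulationConfig",
    "default_class_specs",
    "make_waveform",
    "make_background_noise",
    "simulate_dataset",
    "append_noise_channels",
]


@dataclass(frozen=True)
class WaveformSpec:
    """Clean class waveform: a sum of Gaussian components.

    Each component is ``(amplitude, latency_ms, sigma_ms)`` with the Gaussian
    evaluated as ``A * exp(-(t - mu)^2 / (2 sigma^2))`` so the peak value is
    the amplitude itself.
    """

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for a, mu, sig in self.components:
            if not (math.isfinite(a) and math.isfinite(mu)):
                raise ValueError("waveform component parameters must be finite")
            if sig <= 0:
                raise ValueError(f"component sigma must be positive, got {sig}")


@dataclass(frozen=True)
class NoiseSpec:
    """Target amplitude spectrum of the background activity.

    A ``1/f^alpha`` power-law floor (``spectral_exponent`` is the exponent of
    the *power* spectrum; 0 gives a flat broadband floor) plus a Gaussian
    alpha-band bump. With the default gain the power at the bump center is
    about three times the floor there — a broadband background with a visible
    alpha rhythm, standing in for surrogate realizations of a resting EEG
    recording. The epoch's total noise power is set elsewhere (by the SNR
    scaling), so only the spectrum's shape matters here.
    """

    spectral_exponent: float = 0.0
    alpha_center_hz: float = 10.0
    alpha_bandwidth_hz: float = 2.0
    alpha_gain: float = 0.732  # (1 + g)^2 = 3: alpha power ~3x the floor

    def amplitude_spectrum(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Target (unnormalized) amplitude at each frequency; 0 at DC."""
        f = np.asarray(freqs_hz, dtype=float)
        amp = np.zeros_like(f)
        pos = f > 0
        amp[pos] = f[pos] ** (-self.spectral_exponent / 2.0)
        floor_at_center = self.alpha_center_hz ** (-self.spectral_exponent / 2.0)
        amp += self.alpha_gain * floor_at_center * np.exp(
            -((f - self.alpha_center_hz) ** 2) / (2.0 * self.alpha_bandwidth_hz ** 2)
        )
        amp[~pos] = 0.0
        if np.any(amp[pos] <= 0):
            raise ValueError("noise spec does not yield a strictly positive spectrum")
        return amp


def default_class_specs() -> list[WaveformSpec]:
    """The four benchmark classes (amplitude, latency ms, sigma ms).

    Classes 1 and 2 share the peak latency and have the same pattern energy
    (``A^2 sigma`` matched) but different widths, so they differ in shape, not
    in power; class 3 has a slightly smaller, later peak; class 4 combines two
    smaller Gaussians. Peak amplitude and latency can therefore separate
    {1, 2} from {3, 4} but not the members of each pair.
    """
    return [
        WaveformSpec(((1.0, 150.0, 12.0),)),
        WaveformSpec(((0.65, 150.0, 28.0),)),
        WaveformSpec(((0.8, 210.0, 12.0),)),
        WaveformSpec(((0.55, 190.0, 12.0), (0.55, 265.0, 18.0))),
    ]


@dataclass
class SimulationConfig:
    n_classes: int = 4
    trials_per_class: int = 100
    fs_hz: float = 256.0
    epoch_ms: float = 500.0
    jitter_ms: float = 5.0
    snr: float = 0.33  # clean-pattern power / noise power, per trial
    noise_spec: NoiseSpec = field(default_factory=NoiseSpec)
    n_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_ms < 0:
            raise ValueError("jitter_ms must be >= 0")
        if not (self.snr > 0 or np.isinf(self.snr)):
            raise ValueError("snr must be positive (inf for noiseless)")

    @property
    def n_samples(self) -> int:
        n = self.fs_hz * self.epoch_ms / 1000.0
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs_hz * epoch_ms must give an integer sample count")
        return int(round(n))


def make_waveform(spec: WaveformSpec, jitter_ms: float, fs_hz: float,
                  epoch_ms: float) -> np.ndarray:
    """Sample the clean class waveform with all components shifted by one jitter.

    Raises if any jittered component latency leaves the epoch.
    """
    n = int(round(fs_hz * epoch_ms / 1000.0))
    t = np.arange(n) / fs_hz * 1000.0
    out = np.zeros(n)
    for a, mu, sig in spec.components:
        mu_j = mu + jitter_ms
        if not (0.0 <= mu_j <= epoch_ms):
            raise ValueError(
                f"jittered component latency {mu_j:.1f} ms outside epoch [0, {epoch_ms}] ms"
            )
        out += a * np.exp(-((t - mu_j) ** 2) / (2.0 * sig ** 2))
    return out


def make_background_noise(n_samples: int, noise_spec: NoiseSpec,
                          rng: np.random.Generator,
                          fs_hz: float = 256.0) -> np.ndarray:
    """One realization of phase-randomized, spectrally shaped background noise.

    The target amplitude spectrum is evaluated on the rFFT grid, random phases
    (Hermitian-symmetric by construction of the inverse rFFT) are attached and
    the result inverted to the time domain; the mean is removed. Different RNG
    states give different realizations with the same expected power spectrum.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples of noise")
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    amp = noise_spec.amplitude_spectrum(freqs)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(freqs))
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    if n_samples % 2 == 0:  # Nyquist bin must be real
        spectrum[-1] = amp[-1] * np.where(rng.random() < 0.5, -1.0, 1.0)
    x = np.fft.irfft(spectrum, n=n_samples)
    return x - x.mean()


def simulate_dataset(config: SimulationConfig,
                     class_specs: list[WaveformSpec] | None = None) -> TrialSet:
    """Generate the full labeled benchmark TrialSet.

    Every trial is an independently jittered clean waveform plus a fresh noise
    realization scaled so that (mean clean-pattern power) / (noise power)
    equals ``config.snr`` exactly in that trial. With ``n_channels > 1`` each
    channel carries an independent jitter draw and noise realization for the
    same trial label (independent class information per channel).

    Reproducible from ``config.seed``; channel substreams are spawned so that
    channel ``c`` of an ``n``-channel dataset matches channel ``c`` of any
    wider dataset generated from the same seed.
    """
    if class_specs is None:
        class_specs = default_class_specs()
    if len(class_specs) != config.n_classes:
        raise ValueError(
            f"{len(class_specs)} class specs for n_classes={config.n_classes}"
        )
    n = config.n_samples
    if n & (n - 1) != 0:
        warnings.warn(
            f"epoch of {n} samples is not a power of two; the default wavelet "
            "pipeline requires dyadic epochs (or the padding option)",
            stacklevel=2,
        )
    n_trials = config.n_classes * config.trials_per_class
    labels = np.repeat(np.arange(1, config.n_classes + 1), config.trials_per_class)
    data = np.empty((config.n_channels, n_trials, n))

    root = np.random.SeedSequence(config.seed)
    channel_seeds = root.spawn(config.n_channels)
    noiseless = np.isinf(config.snr)
    for c in range(config.n_channels):
        jitter_rng, noise_rng = (np.random.default_rng(s)
                                 for s in channel_seeds[c].spawn(2))
        t = 0
        for spec in class_specs:
            for _ in range(config.trials_per_class):
                jit = (jitter_rng.uniform(-config.jitter_ms, config.jitter_ms)
                       if config.jitter_ms > 0 else 0.0)
                clean = make_waveform(spec, jit, config.fs_hz, config.epoch_ms)
                if noiseless:
                    data[c, t] = clean
                else:
                    noise = make_background_noise(n, config.noise_spec, noise_rng,
                                                  fs_hz=config.fs_hz)
                    p_sig = np.mean(clean ** 2)
                    p_noise = np.mean(noise ** 2)
                    scale = np.sqrt(p_sig / (config.snr * p_noise))
                    data[c, t] = clean + scale * noise
                t += 1
    return TrialSet(
        data=data,
        labels=labels,
        fs_hz=config.fs_hz,
        t0_ms=0.0,
        channels=[f"sim{c}" for c in range(config.n_channels)],
        provenance={"generator": "wavinfo.simulate", "seed": config.seed,
                    "snr": config.snr, "jitter_ms": config.jitter_ms,
                    "n_classes": config.n_classes,
                    "trials_per_class": config.trials_per_class},
    )


def append_noise_channels(trials: TrialSet, n_noise: int,
                          noise_spec: NoiseSpec | None = None,
                          seed: int = 0) -> TrialSet:
    """Append channels of pure background noise (no class information).

    Each noise trial is scaled to the mean per-trial power of the first
    existing channel so the added channels are realistic in magnitude.
    """
    if noise_spec is None:
        noise_spec = NoiseSpec()
    target_power = float(np.mean(trials.data[0] ** 2))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E3779]))
    data = np.empty((n_noise, trials.n_trials, trials.n_samples))
    for c in range(n_noise):
        for t in range(trials.n_trials):
            x = make_background_noise(trials.n_samples, noise_spec, rng,
                                      fs_hz=trials.fs_hz)
            data[c, t] = x * np.sqrt(target_power / np.mean(x ** 2))
    noise_set = TrialSet(
        data=data,
        labels=trials.labels.copy(),
        fs_hz=trials.fs_hz,
        t0_ms=trials.t0_ms,
        channels=[f"noise{c}" for c in range(n_noise)],
    )
    return trials.merge_channels(noise_set)
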