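"""Single-trial peak-feature baseline decoder.

The comparison method: classify trials from the single-trial peak amplitude
(and optionally latency) of a named component window, using the same
uniform-prior naive-Bayes decoder and leave-one-out protocol as the
wavelet-information pipeline. Trials are linearly detrended first; when the
epoch includes pre-stimulus samples an optional wavelet-denoising step can be
applied, which zeroes post-stimulus coefficients whose magnitude is not
extreme relative to the baseline-period coefficient distribution (a
z-score-thresholded simplification of published ERP denoising schemes, not a
faithful port of any of them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from . import dwt
from .containers import TrialSet
from .decode import DecodingResult, WIConfig, _confusion, fit_naive_bayes, predict

__all__ = [
    "PeakFeature",
    "detrend",
    "denoise",
    "extract_peak",
    "peak_decode",
]


@dataclass(frozen=True)
class PeakFeature:
    """Peak of one trial inside a component window."""

    amplitude: float
    latency_ms: float
    polarity: str  # 'positive' or 'negative'
    window_ms: tuple[float, float]
    edge: bool  # True when no interior local extremum existed


def detrend(trial: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (idempotent)."""
    x = np.asarray(trial, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 samples to detrend")
    return scipy.signal.detrend(x, axis=-1, type="linear")


def extract_peak(trial: np.ndarray, fs_hz: float, window_ms: tuple[float, float],
                 polarity: str = "positive", t0_ms: float = 0.0) -> PeakFeature:
    """Extremum of the stated polarity inside a half-open window.

    Interior local extrema are preferred; when the window holds none (e.g. a
    monotone ramp) the window-edge extremum is returned with ``edge=True``.
    """
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    x = np.asarray(trial, dtype=float)
    times = t0_ms + np.arange(len(x)) / fs_hz * 1000.0
    w0, w1 = window_ms
    epoch_end = t0_ms + len(x) / fs_hz * 1000.0
    if w0 < t0_ms - 1e-9 or w1 > epoch_end + 1e-9 or w1 <= w0:
        raise ValueError(
            f"window [{w0}, {w1}) ms outside epoch [{t0_ms}, {epoch_end}) ms")
    mask = (times >= w0) & (times < w1)
    if not mask.any():
        raise ValueError("window contains no samples")
    seg = x[mask]
    seg_times = times[mask]
    s = seg if polarity == "positive" else -seg
    interior = np.flatnonzero(
        (s[1:-1] >= s[:-2]) & (s[1:-1] >= s[2:])
        & ((s[1:-1] > s[:-2]) | (s[1:-1] > s[2:]))
    ) + 1
    if len(interior):
        best = interior[np.argmax(s[interior])]
        edge = False
    else:
        best = int(np.argmax(s))
        edge = True
    return PeakFeature(
        amplitude=float(seg[best]), latency_ms=float(seg_times[best]),
        polarity=polarity, window_ms=(float(w0), float(w1)), edge=edge)


def denoise(trials: TrialSet, baseline_window_ms: tuple[float, float] | None = None,
            z_threshold: float = 3.0, n_levels: int = 5) -> TrialSet:
    """Zero wavelet coefficients indistinct from the pre-stimulus baseline.

    Per channel and decomposition level, the coefficients whose time support
    falls entirely inside the baseline window (pooled over trials) define a
    reference distribution; every coefficient whose z-score magnitude against
    that distribution is below ``z_threshold`` is zeroed and the trials are
    reconstructed. Levels whose supports are too long to fit inside the
    baseline window are left untouched. With ``z_threshold = 0`` the
    reconstruction is the identity.

    Requires pre-stimulus samples (``t0_ms < 0``); otherwise the operation
    degrades to the identity with a warning.
    """
    if trials.t0_ms >= 0:
        warnings.warn(
            "denoise skipped: epoch has no pre-stimulus samples", stacklevel=2)
        return trials
    if baseline_window_ms is None:
        baseline_window_ms = (trials.t0_ms, 0.0)
    b0, b1 = baseline_window_ms
    if b1 > 0 or b1 <= b0:
        raise ValueError("baseline window must be non-empty and pre-stimulus")
    data = trials.data
    if data.shape[-1] % (1 << n_levels) != 0:
        data = dwt.pad_to_dyadic(data, n_levels)
    coeffs = dwt.decompose_matrix(data, n_levels=n_levels)
    index = dwt.build_index(data.shape[-1], trials.fs_hz, n_levels=n_levels,
                            t0_ms=trials.t0_ms)
    out = np.empty_like(trials.data)
    for ch in range(trials.n_channels):
        c = coeffs[ch]  # (n_trials, F)
        keep = np.zeros_like(c, dtype=bool)
        for lev in np.unique(index.level):
            in_level = index.level == lev
            in_baseline = in_level & (index.support_ms[:, 0] >= b0) \
                & (index.support_ms[:, 1] <= b1 + 1e-9)
            if not in_baseline.any():
                keep[:, in_level] = True  # no baseline reference at this scale
                continue
            ref = c[:, in_baseline].ravel()
            mu, sd = ref.mean(), ref.std()
            if sd == 0:
                sd = 1.0
            z = np.abs((c[:, in_level] - mu) / sd)
            keep[:, in_level] = z >= z_threshold
        masked = np.where(keep, c, 0.0)
        rec = np.stack([
            dwt.reconstruct(masked[t], n_levels=n_levels)
            for t in range(trials.n_trials)
        ])
        out[ch] = rec[:, :trials.n_samples]
    return TrialSet(data=out, labels=trials.labels.copy(), fs_hz=trials.fs_hz,
                    t0_ms=trials.t0_ms, channels=list(trials.channels),
                    provenance=dict(trials.provenance))


def peak_decode(trials: TrialSet, window_ms: tuple[float, float] | None = None,
                polarity: str = "positive", use_latency: bool = False,
                config: WIConfig | None = None, channel: int | str = 0,
                detrend_trials: bool = True, denoise_trials: bool = False,
                z_threshold: float = 3.0) -> DecodingResult:
    """Leave-one-out naive-Bayes decoding from single-trial peak features.

    Features are the peak amplitude (and latency when ``use_latency``) inside
    ``window_ms`` (default: the whole epoch) on the selected channel, after
    linear detrending and, optionally, baseline-referenced denoising. The
    decoder and cross-validation protocol match :func:`wavinfo.decode.loo_decode`.
    """
    if config is None:
        config = WIConfig()
    classes = trials.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if np.sum(trials.labels == c) < 3:
            raise ValueError(f"class {c} has fewer than 3 trials")
    work = trials
    if denoise_trials:
        work = denoise(work, z_threshold=z_threshold)
    ch = work.channels.index(channel) if isinstance(channel, str) else int(channel)
    traces = work.data[ch]
    if detrend_trials:
        traces = detrend(traces)
    if window_ms is None:
        window_ms = (work.t0_ms, work.t0_ms + work.n_samples / work.fs_hz * 1000.0)
    peaks = [extract_peak(traces[t], work.fs_hz, window_ms, polarity=polarity,
                          t0_ms=work.t0_ms) for t in range(work.n_trials)]
    feats = np.array([[p.amplitude, p.latency_ms] for p in peaks])
    if not use_latency:
        feats = feats[:, :1]
    n = work.n_trials
    labels = work.labels
    y_pred = np.empty(n, dtype=labels.dtype)
    all_idx = np.arange(n)
    for i in range(n):
        train = all_idx != i
        model = fit_naive_bayes(feats[train], labels[train])
        y_pred[i], _ = predict(model, feats[i])
    performance = float(np.mean(y_pred == labels))
    return DecodingResult(
        y_true=labels.copy(), y_pred=y_pred, classes=classes,
        performance=performance, confusion=_confusion(labels, y_pred, classes),
        fold_selections=None, index=None,
        method="peak+latency" if use_latency else "peak",
        config=config,
        extras={"window_ms": window_ms, "polarity": polarity,
                "edge_fraction": float(np.mean([p.edge for p in peaks]))})
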