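"""Orthonormal Haar multiresolution decomposition and coefficient bookkeeping.

Single trials are decomposed with an L2-normalized dyadic Haar transform
(scales ``a_j = 2^j``, translations ``b_{j,k} = 2^j k``). A five-level
decomposition of an ``N``-sample epoch yields ``N`` coefficients, concatenated
coarse-to-fine as ``[A5 | D5 | D4 | D3 | D2 | D1]``. For a 256 Hz recording
the detail bands are approximately 64-128 Hz (D1), 32-64 Hz (D2), 16-32 Hz
(D3), 8-16 Hz (D4), 4-8 Hz (D5) and the approximation covers 0-4 Hz (A5).

Because the transform is orthonormal it conserves energy (Parseval) and is
exactly invertible, which the test-suite asserts against an explicitly
constructed Haar basis matrix.

The :class:`CoefficientIndex` maps every coefficient to its channel, level,
translation, frequency band and time support (half-open, 0-based, ms); it is
the substrate for selection tie-breaks and spatiotemporal information maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "CoefficientIndex",
    "WaveletDecomposition",
    "decompose",
    "decompose_matrix",
    "reconstruct",
    "build_index",
    "concat_indices",
    "coeff_lengths",
    "pad_to_dyadic",
]

_WAVELET = "haar"
_MODE = "periodization"  # orthonormal on dyadic lengths


def coeff_lengths(n_samples: int, n_levels: int) -> list[int]:
    """Coefficient block lengths in storage order [A_L, D_L, ..., D_1]."""
    return [n_samples >> n_levels] + [n_samples >> j for j in range(n_levels, 0, -1)]


def _check_dyadic(n: int, n_levels: int) -> None:
    if n % (1 << n_levels) != 0:
        raise ValueError(
            f"signal length {n} is not divisible by 2^{n_levels}; "
            "use pad_to_dyadic() (symmetric reflection) or choose a dyadic epoch"
        )


def pad_to_dyadic(x: np.ndarray, n_levels: int) -> np.ndarray:
    """Reflect-pad the last axis up to the next multiple of ``2^n_levels``."""
    n = x.shape[-1]
    block = 1 << n_levels
    target = ((n + block - 1) // block) * block
    if target == n:
        return np.asarray(x, dtype=float)
    pad = [(0, 0)] * (x.ndim - 1) + [(0, target - n)]
    return np.pad(np.asarray(x, dtype=float), pad, mode="symmetric")


@dataclass
class WaveletDecomposition:
    """Coefficient vector of one trial, aligned to a CoefficientIndex."""

    coefficients: np.ndarray
    n_levels: int
    n_samples: int
    trial_id: int | None = None


@dataclass(frozen=True)
class CoefficientIndex:
    """Per-coefficient bookkeeping: level, translation, band, support, channel.

    ``level_rank`` is 0 for the approximation (coarsest) and increases toward
    D1 (finest); it implements the coarse-first selection tie-break.
    """

    level: np.ndarray  # str, e.g. 'A5', 'D4'
    level_rank: np.ndarray  # int, 0 = A_L ... L = D1
    k: np.ndarray  # translation within level
    band_hz: np.ndarray  # (n, 2) low/high edge
    support_ms: np.ndarray  # (n, 2) half-open [start, end)
    channel: np.ndarray  # str channel name per coefficient
    channel_idx: np.ndarray  # int channel position
    n_samples: int
    fs_hz: float
    n_levels: int

    def __len__(self) -> int:
        return len(self.level)

    def tie_break_order(self) -> np.ndarray:
        """Deterministic ranking order used to break equal-information ties.

        Coarser level first, then earlier time support, then channel order.
        """
        return np.lexsort(
            (self.channel_idx, self.support_ms[:, 0], self.level_rank)
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "coeff_id": np.arange(len(self)),
                "channel": self.channel,
                "level": self.level,
                "k": self.k,
                "band_low_hz": self.band_hz[:, 0],
                "band_high_hz": self.band_hz[:, 1],
                "support_start_ms": self.support_ms[:, 0],
                "support_end_ms": self.support_ms[:, 1],
            }
        )


def decompose_matrix(signals: np.ndarray, n_levels: int = 5) -> np.ndarray:
    """Decompose signals along the last axis; returns same-shape coefficients.

    Coefficients are concatenated ``[A_L | D_L | ... | D_1]``, each block in
    time-ascending translation order.
    """
    signals = np.asarray(signals, dtype=float)
    _check_dyadic(signals.shape[-1], n_levels)
    coeffs = pywt.wavedec(signals, _WAVELET, mode=_MODE, level=n_levels, axis=-1)
    return np.concatenate(coeffs, axis=-1)


def decompose(signal: np.ndarray, n_levels: int = 5,
              trial_id: int | None = None) -> WaveletDecomposition:
    """Five-level (by default) orthonormal Haar decomposition of one trace."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("decompose expects a 1-D trace; see decompose_matrix")
    c = decompose_matrix(signal, n_levels=n_levels)
    return WaveletDecomposition(c, n_levels=n_levels, n_samples=len(signal),
                                trial_id=trial_id)


def reconstruct(decomp: WaveletDecomposition | np.ndarray,
                keep_mask: np.ndarray | None = None,
                n_levels: int | None = None) -> np.ndarray:
    """Inverse transform, optionally zeroing the coefficients not in ``keep_mask``."""
    if isinstance(decomp, WaveletDecomposition):
        coeffs, n_levels = decomp.coefficients, decomp.n_levels
    else:
        coeffs = np.asarray(decomp, dtype=float)
        if n_levels is None:
            raise ValueError("n_levels required when passing a raw coefficient array")
    coeffs = np.array(coeffs, dtype=float, copy=True)
    if keep_mask is not None:
        keep_mask = np.asarray(keep_mask, dtype=bool)
        if keep_mask.shape != coeffs.shape:
            raise ValueError("keep_mask shape must match the coefficient vector")
        coeffs[~keep_mask] = 0.0
    lengths = coeff_lengths(len(coeffs), n_levels)
    parts = np.split(coeffs, np.cumsum(lengths)[:-1])
    return pywt.waverec(list(parts), _WAVELET, mode=_MODE)


def build_index(n_samples: int, fs_hz: float, n_levels: int = 5,
                channel: str = "ch0", channel_idx: int = 0,
                t0_ms: float = 0.0) -> CoefficientIndex:
    """Bookkeeping for one channel's coefficient vector.

    Time supports are half-open ``[k 2^j, (k+1) 2^j)`` in samples, converted to
    ms relative to stimulus onset. Frequency bands follow dyadic halving of the
    Nyquist frequency.
    """
    _check_dyadic(n_samples, n_levels)
    levels, ranks, ks, bands, supports = [], [], [], [], []
    sample_ms = 1000.0 / fs_hz
    # approximation block A_L
    n_a = n_samples >> n_levels
    for k in range(n_a):
        levels.append(f"A{n_levels}")
        ranks.append(0)
        ks.append(k)
        bands.append((0.0, fs_hz / 2 ** (n_levels + 1)))
        supports.append((t0_ms + k * (1 << n_levels) * sample_ms,
                         t0_ms + (k + 1) * (1 << n_levels) * sample_ms))
    # detail blocks D_L ... D_1
    for j in range(n_levels, 0, -1):
        n_d = n_samples >> j
        for k in range(n_d):
            levels.append(f"D{j}")
            ranks.append(n_levels - j + 1)
            ks.append(k)
            bands.append((fs_hz / 2 ** (j + 1), fs_hz / 2 ** j))
            supports.append((t0_ms + k * (1 << j) * sample_ms,
                             t0_ms + (k + 1) * (1 << j) * sample_ms))
    return CoefficientIndex(
        level=np.array(levels),
        level_rank=np.array(ranks),
        k=np.array(ks),
        band_hz=np.array(bands, dtype=float),
        support_ms=np.array(supports, dtype=float),
        channel=np.array([channel] * n_samples),
        channel_idx=np.full(n_samples, channel_idx, dtype=int),
        n_samples=n_samples,
        fs_hz=fs_hz,
        n_levels=n_levels,
    )


def concat_indices(indices: list[CoefficientIndex]) -> CoefficientIndex:
    """Concatenate per-channel indices into one channel-qualified index."""
    first = indices[0]
    for ix in indices[1:]:
        if ix.n_samples != first.n_samples or ix.fs_hz != first.fs_hz \
                or ix.n_levels != first.n_levels:
            raise ValueError("indices to concatenate must share geometry")
    return CoefficientIndex(
        level=np.concatenate([ix.level for ix in indices]),
        level_rank=np.concatenate([ix.level_rank for ix in indices]),
        k=np.concatenate([ix.k for ix in indices]),
        band_hz=np.concatenate([ix.band_hz for ix in indices]),
        support_ms=np.concatenate([ix.support_ms for ix in indices]),
        channel=np.concatenate([ix.channel for ix in indices]),
        channel_idx=np.concatenate(
            [np.full(len(ix), i, dtype=int) for i, ix in enumerate(indices)]
        ),
        n_samples=first.n_samples,
        fs_hz=first.fs_hz,
        n_levels=first.n_levels,
    )


def build_index_multichannel(n_samples: int, fs_hz: float, channels: list[str],
                             n_levels: int = 5, t0_ms: float = 0.0) -> CoefficientIndex:
    """Channel-qualified index for a multichannel coefficient pool."""
    return concat_indices([
        build_index(n_samples, fs_hz, n_levels=n_levels, channel=ch,
                    channel_idx=i, t0_ms=t0_ms)
        for i, ch in enumerate(channels)
    ])
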