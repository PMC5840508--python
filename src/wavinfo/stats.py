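"""Permutation significance and spatiotemporal selection-rate maps.

Significance of a decoding performance is assessed by rerunning the entire
pipeline (including per-fold coefficient selection) on label-shuffled copies
of the data; the p-value is the proportion of shuffle performances strictly
above the observed one, so its resolution is ``1 / n_shuffles``. An optional
add-one correction ``(r + 1) / (n + 1)`` is available for users who need a
nonzero p-value.

Selection-rate maps summarize where and when discriminative information
lives: per coefficient, the fraction of leave-one-out folds in which it was
selected; aggregated per (channel, post-stimulus sample) as the mean rate of
the ``n_levels + 1`` coefficients (one per decomposition scale) whose time
support covers that sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import TrialSet
from .decode import DecodingResult, WIConfig, loo_decode
from .dwt import CoefficientIndex

__all__ = ["NullDistribution", "SelectionRateMap", "permutation_null",
           "selection_rate_map"]


@dataclass
class NullDistribution:
    shuffle_performances: np.ndarray
    observed_performance: float
    p_value: float
    n_shuffles: int
    p_correction: str = "none"


@dataclass
class SelectionRateMap:
    """Coefficient-level and channel x time selection rates."""

    coeff_rate: np.ndarray  # (n_coefficients,) fraction of folds selected
    channel_time: np.ndarray  # (n_channels, n_samples) mean over covering scales
    channels: list[str]
    times_ms: np.ndarray
    index: CoefficientIndex

    def to_frame(self):
        """Long-format table: channel, time_ms, level, rate (per coefficient-sample)."""
        import pandas as pd

        ix = self.index
        sample_ms = 1000.0 / ix.fs_hz
        rows = []
        for cid in range(len(ix)):
            s0, s1 = ix.support_ms[cid]
            t = s0
            while t < s1 - 1e-9:
                rows.append((ix.channel[cid], t, ix.level[cid],
                             self.coeff_rate[cid]))
                t += sample_ms
        return pd.DataFrame(rows, columns=["channel", "time_ms", "level", "rate"])


def _shuffle_labels(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return labels[rng.permutation(len(labels))]


def permutation_null(trials: TrialSet, config: WIConfig | None = None,
                     n_shuffles: int = 100, seed: int | None = None,
                     observed: float | None = None,
                     p_correction: str = "none") -> NullDistribution:
    """Label-shuffle null distribution of decoding performance.

    Every shuffle permutes the trial labels (class counts preserved) and
    reruns the full leave-one-out pipeline with an independent RNG substream
    keyed by ``(seed, shuffle_index)``. ``observed`` can be supplied to reuse
    an already-computed performance; otherwise it is computed first.
    """
    if config is None:
        config = WIConfig()
    if seed is None:
        seed = config.seed
    if p_correction not in ("none", "add-one"):
        raise ValueError("p_correction must be 'none' or 'add-one'")
    if observed is None:
        observed = loo_decode(trials, config).performance
    perf = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2, s]))
        shuffled = trials.with_labels(_shuffle_labels(trials.labels, perm_rng))
        inner_seed = int(
            np.random.SeedSequence([int(seed), 1, s]).generate_state(1)[0]
            % (2 ** 31))
        cfg = WIConfig(**{**config.__dict__, "seed": inner_seed})
        perf[s] = loo_decode(shuffled, cfg).performance
    r = int(np.sum(perf > observed))
    if p_correction == "add-one":
        p = (r + 1) / (n_shuffles + 1)
    else:
        p = r / n_shuffles
    return NullDistribution(
        shuffle_performances=perf, observed_performance=float(observed),
        p_value=float(p), n_shuffles=n_shuffles, p_correction=p_correction)


def selection_rate_map(result: DecodingResult,
                       index: CoefficientIndex | None = None) -> SelectionRateMap:
    """Selection rates per coefficient and per (channel, time sample).

    Requires a decoding result that retained per-fold selections and a
    channel-qualified coefficient index (taken from the result itself when
    not passed explicitly).
    """
    if result.fold_selections is None:
        raise ValueError("decoding result does not retain per-fold selections")
    if index is None:
        index = result.index
    if index is None:
        raise ValueError("a CoefficientIndex is required to map selections")
    n_folds = result.fold_selections.shape[0]
    counts = np.bincount(result.fold_selections.ravel(), minlength=len(index))
    rate = counts / n_folds

    channels = list(dict.fromkeys(index.channel.tolist()))
    fs = index.fs_hz
    n_samples = index.n_samples
    t0 = float(index.support_ms[:, 0].min())
    times = t0 + np.arange(n_samples) / fs * 1000.0
    sample_ms = 1000.0 / fs
    grid = np.zeros((len(channels), n_samples))
    for cid in range(len(index)):
        ch = int(index.channel_idx[cid])
        s0 = int(round((index.support_ms[cid, 0] - t0) / sample_ms))
        s1 = int(round((index.support_ms[cid, 1] - t0) / sample_ms))
        grid[ch, s0:s1] += rate[cid]
    grid /= index.n_levels + 1  # one coefficient per scale covers each sample
    return SelectionRateMap(coeff_rate=rate, channel_time=grid,
                            channels=channels, times_ms=times, index=index)
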