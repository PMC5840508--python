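"""Information-driven wavelet-coefficient selection.

Single-trial coefficients are too noisy for stable information ranking, so
each coefficient's mutual information with the class labels is estimated from
bootstrap *sub-ensemble averages*: by default 200 averages per class, each the
mean of 30 trials drawn with replacement from that class. Coefficient values
are quantized into ``2^n_bits`` equal-width bins spanning the min-max range of
the sub-average values (training data only), and the plug-in mutual
information of the (class, bin) joint histogram is computed in bits. The top
``K`` coefficients (default 25) by estimated information are kept.

The estimator is deliberately simple: the goal is ranking coefficients, not
unbiased information estimation, so no bias correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dwt import CoefficientIndex

__all__ = [
    "InformationTable",
    "Selection",
    "subensemble_averages",
    "quantize",
    "mutual_information",
    "coefficient_information",
    "rank_and_select",
]


@dataclass
class InformationTable:
    """Estimated information (bits) per coefficient, plus estimation metadata."""

    info_bits: np.ndarray
    index: CoefficientIndex | None = None
    n_subaverages: int = 200
    trials_per_average: int = 30
    n_bits_quantization: int = 2

    def __len__(self) -> int:
        return len(self.info_bits)


@dataclass
class Selection:
    """Ordered coefficient ids (descending information, documented tie-break)."""

    coeff_ids: np.ndarray
    info_bits: np.ndarray

    @property
    def k(self) -> int:
        return len(self.coeff_ids)


def _class_partition(labels: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    classes = np.unique(labels)
    if len(classes) == 0:
        raise ValueError("no trials: every class must have at least one trial")
    idx = [np.flatnonzero(labels == c) for c in classes]
    for c, ix in zip(classes, idx):
        if len(ix) == 0:
            raise ValueError(f"class {c} has no trials")
    return classes, idx


def subensemble_averages(features: np.ndarray, labels: np.ndarray,
                         n_averages: int = 200, trials_per_average: int = 30,
                         rng: np.random.Generator | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap sub-ensemble averages per class.

    Parameters
    ----------
    features:
        ``(n_trials, n_features)`` matrix (trial traces or coefficient
        vectors — averaging commutes with the linear wavelet transform).
    labels:
        Class id per trial.

    Returns
    -------
    (averages, average_labels):
        ``(n_classes * n_averages, n_features)`` stacked class blocks in
        sorted class order, each row the mean of ``trials_per_average`` trials
        drawn with replacement from one class, and the matching labels.
    """
    if rng is None:
        rng = np.random.default_rng()
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    labels = np.asarray(labels)
    if len(labels) != features.shape[0]:
        raise ValueError("labels length must match number of trials")
    classes, class_idx = _class_partition(labels)
    blocks, out_labels = [], []
    for c, idx in zip(classes, class_idx):
        blocks.append(_bootstrap_block(features, idx, n_averages,
                                       trials_per_average, rng))
        out_labels.append(np.full(n_averages, c, dtype=labels.dtype))
    return np.concatenate(blocks, axis=0), np.concatenate(out_labels)


def _bootstrap_block(features: np.ndarray, idx: np.ndarray, n_averages: int,
                     trials_per_average: int, rng: np.random.Generator
                     ) -> np.ndarray:
    """Mean of with-replacement draws, computed as a count-matrix product."""
    m = len(idx)
    draws = rng.integers(0, m, size=(n_averages, trials_per_average))
    flat = draws + (np.arange(n_averages)[:, None] * m)
    counts = np.bincount(flat.ravel(), minlength=n_averages * m)
    counts = counts.reshape(n_averages, m).astype(float)
    return counts @ features[idx] / trials_per_average


def quantize(values: np.ndarray, n_bits: int = 2) -> np.ndarray:
    """Equal-width binning over the min-max range of ``values``.

    Works per column on 2-D input. The maximum maps to the top bin; a constant
    column maps entirely to bin 0.
    """
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    squeeze = v.ndim == 1
    if squeeze:
        v = v[:, None]
    nb = 1 << n_bits
    lo = v.min(axis=0)
    span = v.max(axis=0) - lo
    scale = np.where(span > 0, nb / np.where(span > 0, span, 1.0), 0.0)
    bins = ((v - lo) * scale).astype(np.int64)
    np.clip(bins, 0, nb - 1, out=bins)
    return bins[:, 0] if squeeze else bins


def _info_from_joint_counts(counts: np.ndarray) -> np.ndarray:
    """Plug-in MI in bits from ``(..., n_classes, n_bins)`` count tables."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=(-2, -1), keepdims=True)
    p = counts / n
    ps = p.sum(axis=-1, keepdims=True)
    pw = p.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (ps * pw))
    terms[~np.isfinite(terms)] = 0.0  # 0 log 0 := 0
    return terms.sum(axis=(-2, -1))


def mutual_information(bin_indices: np.ndarray, labels: np.ndarray) -> float:
    """Plug-in mutual information (bits) between bin index and class label."""
    bins = np.asarray(bin_indices)
    labels = np.asarray(labels)
    if bins.shape != labels.shape:
        raise ValueError("bin_indices and labels must have equal length")
    classes, class_codes = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for mutual information")
    bvals, bin_codes = np.unique(bins, return_inverse=True)
    counts = np.zeros((len(classes), len(bvals)))
    np.add.at(counts, (class_codes, bin_codes), 1.0)
    return float(_info_from_joint_counts(counts))


def information_matrix(values: np.ndarray, labels: np.ndarray,
                       n_bits: int = 2) -> np.ndarray:
    """Quantize every column of ``values`` and return MI with labels, per column.

    Vectorized core used inside the cross-validation loop.
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes, class_codes = np.unique(labels, return_inverse=True)
    n_classes = len(classes)
    nb = 1 << n_bits
    bins = quantize(v, n_bits=n_bits)  # (N, F)
    n_obs, n_feat = bins.shape
    cell = bins + nb * class_codes[:, None] \
        + (nb * n_classes) * np.arange(n_feat)[None, :]
    counts = np.bincount(cell.ravel(), minlength=n_feat * n_classes * nb)
    counts = counts.reshape(n_feat, n_classes, nb)
    return _info_from_joint_counts(counts)


def coefficient_information(coeffs: np.ndarray, labels: np.ndarray,
                            n_subaverages: int = 200,
                            trials_per_average: int = 30,
                            n_bits: int = 2,
                            rng: np.random.Generator | None = None,
                            index: CoefficientIndex | None = None
                            ) -> InformationTable:
    """Full information estimate: sub-ensemble averaging, quantization, MI.

    ``coeffs`` is the ``(n_trials, n_coefficients)`` matrix of wavelet
    coefficients (possibly channel-concatenated).
    """
    averages, avg_labels = subensemble_averages(
        coeffs, labels, n_averages=n_subaverages,
        trials_per_average=trials_per_average, rng=rng)
    info = information_matrix(averages, avg_labels, n_bits=n_bits)
    return InformationTable(info_bits=info, index=index,
                            n_subaverages=n_subaverages,
                            trials_per_average=trials_per_average,
                            n_bits_quantization=n_bits)


def rank_and_select(info: InformationTable, k: int = 25,
                    valid: np.ndarray | None = None) -> Selection:
    """Top-``k`` coefficients by information with a deterministic tie-break.

    Ties are broken coarser-level-first, then earlier time support, then
    channel order (requires ``info.index``); without an index, ties fall back
    to coefficient-id order. ``valid`` optionally masks coefficients out of
    the ranking (e.g. padding artifacts).
    """
    values = np.asarray(info.info_bits, dtype=float)
    n = len(values)
    if k > n:
        raise ValueError(f"cannot select k={k} from {n} coefficients")
    if info.index is not None:
        order = info.index.tie_break_order()
    else:
        order = np.arange(n)
    if valid is not None:
        order = order[np.asarray(valid, dtype=bool)[order]]
        if k > len(order):
            raise ValueError(f"cannot select k={k} from {len(order)} valid coefficients")
    ranked = order[np.argsort(-values[order], kind="stable")]
    chosen = ranked[:k]
    return Selection(coeff_ids=chosen, info_bits=values[chosen])
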