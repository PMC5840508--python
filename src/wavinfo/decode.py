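"""Uniform-prior naive-Bayes decoding under leave-one-out cross-validation.

Each held-out trial is classified by a model built exclusively from the
remaining trials: the sub-ensemble averaging, information estimation and
top-K coefficient selection are all recomputed inside the fold, so the test
trial influences neither feature selection nor model fitting. Decoding
performance is the proportion of trials correctly classified.

The per-(class, coefficient) likelihood is a one-dimensional Gaussian with a
variance floor; class priors are uniform regardless of class counts. For
multichannel data the coefficients of all channels form one pool, information
is estimated per coefficient, and the global top-K are selected with no
constraint on how many come from any one channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dwt
from .containers import TrialSet
from .select import (InformationTable, Selection, coefficient_information,
                     rank_and_select)

__all__ = [
    "WIConfig",
    "NaiveBayesModel",
    "DecodingResult",
    "fit_naive_bayes",
    "predict",
    "loo_decode",
    "pool_channels",
    "fold_rng",
]

_VAR_FLOOR_REL = 1e-9


@dataclass
class WIConfig:
    """Parameters of the wavelet-information pipeline."""

    n_levels: int = 5
    n_subaverages: int = 200
    trials_per_average: int = 30
    quant_bits: int = 2
    n_select: int = 25
    seed: int = 0
    pad_non_dyadic: bool = False


@dataclass
class NaiveBayesModel:
    classes: np.ndarray
    means: np.ndarray  # (n_classes, n_features)
    variances: np.ndarray  # (n_classes, n_features), floored

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


@dataclass
class DecodingResult:
    """Per-trial predictions plus aggregates of one cross-validated run."""

    y_true: np.ndarray
    y_pred: np.ndarray
    classes: np.ndarray
    performance: float
    confusion: np.ndarray  # rows true class (sorted), columns predicted, row-normalized
    fold_selections: np.ndarray | None = None  # (n_folds, k) coefficient ids
    index: dwt.CoefficientIndex | None = None
    method: str = "wi"
    config: WIConfig | None = None
    extras: dict = field(default_factory=dict)


def fit_naive_bayes(features: np.ndarray, labels: np.ndarray) -> NaiveBayesModel:
    """Per-class, per-feature Gaussian likelihoods with a variance floor.

    The floor is ``1e-9`` times the pooled per-feature variance (features with
    zero pooled variance get an absolute floor of ``1e-9``), keeping
    log-likelihoods finite on degenerate training sets.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit a decoder")
    counts = np.array([np.sum(y == c) for c in classes])
    if np.any(counts < 2):
        bad = classes[counts < 2][0]
        raise ValueError(f"class {bad} has fewer than 2 training trials")
    pooled = X.var(axis=0)
    floor = _VAR_FLOOR_REL * np.where(pooled > 0, pooled, 1.0)
    means = np.empty((len(classes), X.shape[1]))
    variances = np.empty_like(means)
    for i, c in enumerate(classes):
        Xc = X[y == c]
        means[i] = Xc.mean(axis=0)
        variances[i] = np.maximum(Xc.var(axis=0), floor)
    return NaiveBayesModel(classes=classes, means=means, variances=variances)


def _log_likelihoods(model: NaiveBayesModel, X: np.ndarray) -> np.ndarray:
    """(n_obs, n_classes) Gaussian log-likelihood sums over features."""
    d = X[:, None, :] - model.means[None, :, :]
    return -0.5 * np.sum(d * d / model.variances[None]
                         + np.log(2.0 * np.pi * model.variances[None]), axis=2)


def predict(model: NaiveBayesModel, features: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class and normalized posterior per observation.

    Uniform priors add a constant to every class score, so prediction is the
    argmax of summed log-likelihoods; exact ties resolve to the first class in
    model order.
    """
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.n_features})"
        )
    ll = _log_likelihoods(model, X)
    pred = model.classes[np.argmax(ll, axis=1)]
    shifted = ll - ll.max(axis=1, keepdims=True)
    post = np.exp(shifted)
    post /= post.sum(axis=1, keepdims=True)
    if single:
        return pred[0], post[0]
    return pred, post


def fold_rng(seed: int, fold: int) -> np.random.Generator:
    """Dedicated RNG substream for one cross-validation fold."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(fold)]))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray
               ) -> np.ndarray:
    cm = np.zeros((len(classes), len(classes)))
    pos = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        cm[pos[t], pos[p]] += 1.0
    rows = cm.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return cm / rows


def _decompose_trialset(trials: TrialSet, config: WIConfig
                        ) -> tuple[np.ndarray, dwt.CoefficientIndex, np.ndarray]:
    """All-trial coefficient matrix (n_trials, n_channels*n_samples) + index.

    Returns a validity mask that excludes coefficients whose support lies
    beyond the original epoch when reflection padding was applied.
    """
    data = trials.data
    if data.shape[-1] % (1 << config.n_levels) != 0:
        if not config.pad_non_dyadic:
            raise ValueError(
                f"epoch of {data.shape[-1]} samples is not divisible by "
                f"2^{config.n_levels}; set pad_non_dyadic=True to reflect-pad"
            )
        data = dwt.pad_to_dyadic(data, config.n_levels)
    coeffs = dwt.decompose_matrix(data, n_levels=config.n_levels)
    n_samples_padded = data.shape[-1]
    index = dwt.build_index_multichannel(
        n_samples_padded, trials.fs_hz, trials.channels,
        n_levels=config.n_levels, t0_ms=trials.t0_ms)
    epoch_end = trials.t0_ms + trials.n_samples / trials.fs_hz * 1000.0
    valid = index.support_ms[:, 0] < epoch_end - 1e-9
    # (n_channels, n_trials, F) -> (n_trials, n_channels*F)
    feat = np.transpose(coeffs, (1, 0, 2)).reshape(trials.n_trials, -1)
    return feat, index, valid


def select_and_fit(features_train: np.ndarray, labels_train: np.ndarray,
                   index: dwt.CoefficientIndex, config: WIConfig,
                   rng: np.random.Generator,
                   valid: np.ndarray | None = None
                   ) -> tuple[Selection, NaiveBayesModel]:
    """One fold's feature selection + model fit from training trials only.

    Exposed so the no-leakage contract can be exercised directly: rerunning
    this on the training set of a fold (same RNG substream) reproduces that
    fold's selection and prediction bit-exactly.
    """
    table = coefficient_information(
        features_train, labels_train,
        n_subaverages=config.n_subaverages,
        trials_per_average=config.trials_per_average,
        n_bits=config.quant_bits, rng=rng, index=index)
    selection = rank_and_select(table, k=config.n_select, valid=valid)
    model = fit_naive_bayes(features_train[:, selection.coeff_ids], labels_train)
    return selection, model


def loo_decode(trials: TrialSet, config: WIConfig | None = None) -> DecodingResult:
    """Leave-one-out wavelet-information decoding of a TrialSet.

    For every fold the held-out trial is removed, sub-ensemble averages are
    drawn from the remaining trials (fold-specific RNG substream keyed by
    ``(config.seed, trial_index)``), coefficient information is estimated,
    the top-K pool over all channels is selected, a uniform-prior Gaussian
    naive-Bayes model is fit on the remaining trials' selected coefficients,
    and the held-out trial is classified.
    """
    if config is None:
        config = WIConfig()
    classes = trials.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if np.sum(trials.labels == c) < 3:
            raise ValueError(f"class {c} has fewer than 3 trials")
    feat, index, valid = _decompose_trialset(trials, config)
    valid_arg = None if valid.all() else valid
    n = trials.n_trials
    labels = trials.labels
    all_idx = np.arange(n)
    y_pred = np.empty(n, dtype=labels.dtype)
    selections = np.empty((n, config.n_select), dtype=int)
    for i in range(n):
        train = all_idx != i
        rng = fold_rng(config.seed, i)
        selection, model = select_and_fit(
            feat[train], labels[train], index, config, rng, valid=valid_arg)
        pred, _ = predict(model, feat[i, selection.coeff_ids])
        y_pred[i] = pred
        selections[i] = selection.coeff_ids
    performance = float(np.mean(y_pred == labels))
    return DecodingResult(
        y_true=labels.copy(), y_pred=y_pred, classes=classes,
        performance=performance,
        confusion=_confusion(labels, y_pred, classes),
        fold_selections=selections, index=index, method="wi", config=config)


def pool_channels(per_channel_info: list[InformationTable], k: int = 25
                  ) -> Selection:
    """Global top-``k`` over channel-qualified coefficient pools.

    Concatenates per-channel information tables (which must share estimation
    parameters) and ranks the joint pool; a single channel may contribute all
    ``k`` selected coefficients. Returned ids are offsets into the
    concatenated pool.
    """
    if not per_channel_info:
        raise ValueError("no information tables to pool")
    first = per_channel_info[0]
    for t in per_channel_info[1:]:
        if (t.n_subaverages, t.trials_per_average, t.n_bits_quantization) != \
                (first.n_subaverages, first.trials_per_average,
                 first.n_bits_quantization):
            raise ValueError("information tables have mismatched selection parameters")
    info = np.concatenate([t.info_bits for t in per_channel_info])
    if all(t.index is not None for t in per_channel_info):
        index = dwt.concat_indices([t.index for t in per_channel_info])
        # re-qualify channel order by pool position
        index = dwt.CoefficientIndex(
            level=index.level, level_rank=index.level_rank, k=index.k,
            band_hz=index.band_hz, support_ms=index.support_ms,
            channel=index.channel,
            channel_idx=np.repeat(np.arange(len(per_channel_info)),
                                  [len(t) for t in per_channel_info]),
            n_samples=index.n_samples, fs_hz=index.fs_hz,
            n_levels=index.n_levels)
    else:
        index = None
    table = InformationTable(
        info_bits=info, index=index,
        n_subaverages=first.n_subaverages,
        trials_per_average=first.trials_per_average,
        n_bits_quantization=first.n_bits_quantization)
    return rank_and_select(table, k=k)
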