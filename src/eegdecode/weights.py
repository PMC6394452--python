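"""Linear-model feature weights: Haufe correction and channel-level maps.

Raw weight vectors of a linear backward model (an SVM decision boundary)
are not directly interpretable as signal topographies: a channel can carry a
large weight purely to cancel noise it shares with informative channels. The
corrective transformation multiplies the weight vector by the empirical
feature covariance of the training data, turning the extraction filter
``w`` into an activation pattern

    a = Cov(X) w / Var(w^T X),

the single-component form of the forward-model transformation. Activation
patterns are near zero for channels whose activity is uncorrelated with the
decoded signal, however large their raw weights.

For group-level maps the (corrected) weights are averaged over the
timepoints of each channel within the analysis window, rectified, and
z-standardised across channels within each analysis step, yielding one
absolute, z-scored value per channel per window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateDataError

#: relative tolerance below which the across-channel SD counts as zero
_DEGENERATE_SD_RTOL = 1e-12


def haufe_correct(weights: np.ndarray, train_vectors: np.ndarray) -> np.ndarray:
    """Transform an extraction filter into an activation pattern.

    Parameters
    ----------
    weights
        Linear-model weight vector, length ``n_features``.
    train_vectors
        Training data, shape ``(n_exemplars, n_features)`` with
        ``n_exemplars >= 2`` (needed for an empirical covariance).

    Returns
    -------
    Activation pattern ``a = Cov(X) w / Var(w^T X)``, same length as
    ``weights``.
    """
    w = np.asarray(weights, dtype=np.float64).ravel()
    X = np.asarray(train_vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != w.size:
        raise ConfigurationError(
            f"weights length {w.size} does not match {X.shape} training data"
        )
    if X.shape[0] < 2:
        raise DegenerateDataError("Haufe correction needs >= 2 training exemplars")
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    sigma_w = Xc.T @ (Xc @ w) / (n - 1)  # Cov(X) w without forming Cov(X)
    proj_var = float(w @ sigma_w)
    if proj_var <= 0:
        raise DegenerateDataError(
            "projected score variance is zero; activation pattern undefined"
        )
    return sigma_w / proj_var


def reduce_to_channels(
    weights: np.ndarray,
    layout: Sequence[tuple[int, int | None]],
    mode: str,
) -> np.ndarray:
    """Reduce per-feature weights to absolute, z-scored per-channel values.

    ``weights`` may be one step (``(n_features,)``) or a stack
    (``(n_steps, n_features)``). Per channel, the weights of its window
    timepoints are averaged (signed), rectified, then z-standardised across
    channels within each step. Temporal mode has one channel only, so a
    channel map is not defined for it.
    """
    if mode not in ("spatial", "spatiotemporal"):
        raise ConfigurationError(
            f"channel-level weight maps are only defined for spatial and "
            f"spatiotemporal analyses, not '{mode}'"
        )
    W = np.atleast_2d(np.asarray(weights, dtype=np.float64))
    channels = sorted({ch for ch, _ in layout})
    n_ch = len(channels)
    ch_index = {ch: i for i, ch in enumerate(channels)}
    sums = np.zeros((W.shape[0], n_ch))
    counts = np.zeros(n_ch)
    for pos, (ch, _) in enumerate(layout):
        sums[:, ch_index[ch]] += W[:, pos]
        counts[ch_index[ch]] += 1
    per_channel = np.abs(sums / counts)
    mean = per_channel.mean(axis=1, keepdims=True)
    sd = per_channel.std(axis=1, ddof=0, keepdims=True)
    cutoff = np.maximum(np.abs(mean), 1.0) * _DEGENERATE_SD_RTOL
    degenerate = (sd <= cutoff).ravel()
    if degenerate.any():
        warnings.warn(
            "zero across-channel SD in at least one analysis step; "
            "z-scores set to 0",
            stacklevel=2,
        )
    sd = np.where(sd <= cutoff, 1.0, sd)
    z = (per_channel - mean) / sd
    z[degenerate] = 0.0
    if np.asarray(weights).ndim == 1:
        return z[0]
    return z


@dataclass
class FeatureWeightMap:
    """Feature weights of one decoding analysis.

    ``raw`` and ``corrected`` are signed per-feature weights averaged over
    all cross-validated analyses (shape ``(n_steps, n_features)``);
    ``per_channel`` holds the absolute, z-standardised, timepoint-averaged
    channel values (shape ``(n_steps, n_channels)``) computed from the
    corrected weights, where defined.
    """

    raw: np.ndarray
    corrected: np.ndarray
    per_channel: np.ndarray | None
    feature_layout: tuple[tuple[int, int | None], ...]
    mode: str

    @classmethod
    def from_mean_weights(
        cls,
        raw: np.ndarray,
        corrected: np.ndarray,
        layout: Sequence[tuple[int, int | None]],
        mode: str,
    ) -> "FeatureWeightMap":
        per_channel = None
        if mode in ("spatial", "spatiotemporal"):
            per_channel = reduce_to_channels(corrected, layout, mode)
        return cls(
            raw=np.asarray(raw, dtype=np.float64),
            corrected=np.asarray(corrected, dtype=np.float64),
            per_channel=per_channel,
            feature_layout=tuple(layout),
            mode=mode,
        )
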