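"""Analysis-window planning and per-trial feature-vector extraction.

A decoding analysis slides a fixed-width window through the epoch at a fixed
step. Each window yields one pattern matrix per condition whose rows are
trials and whose columns are features:

- ``spatial``: the within-window time-average of each channel
  (``n_channels`` features);
- ``temporal``: the raw within-window samples of one chosen channel
  (``width`` features);
- ``spatiotemporal``: all within-window samples of all channels in
  channel-major order (``n_channels * width`` features).

Channel-major ordering (all timepoints of channel 1, then channel 2, ...)
is fixed so that feature weights can later be averaged per channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EpochedDataset
from .errors import ConditionLookupError, ConfigurationError


@dataclass(frozen=True)
class WindowPlan:
    """Grid of analysis windows over an epoch.

    ``starts`` holds 0-based sample indices of window onsets; windows that
    would extend past the epoch end are dropped, never truncated, so the
    feature dimensionality is constant across steps.
    """

    starts: tuple[int, ...]
    width_samples: int
    step_samples: int

    @property
    def n_steps(self) -> int:
        return len(self.starts)

    def window_times_ms(
        self, sampling_rate_hz: float, epoch_start_ms: float = 0.0
    ) -> np.ndarray:
        """(n_steps, 2) array of window [start, end) times in ms."""
        dt = 1000.0 / sampling_rate_hz
        starts = np.asarray(self.starts, dtype=float)
        return np.column_stack(
            [
                epoch_start_ms + starts * dt,
                epoch_start_ms + (starts + self.width_samples) * dt,
            ]
        )


def make_window_plan(n_timepoints: int, width: int, step: int) -> WindowPlan:
    """Build the window grid for an epoch of ``n_timepoints`` samples.

    The number of steps is ``floor((T - width) / step) + 1``.
    """
    if width < 1 or step < 1:
        raise ConfigurationError("window width and step must be >= 1 sample")
    if width > n_timepoints:
        raise ConfigurationError(
            f"window width {width} exceeds epoch length {n_timepoints}"
        )
    n_steps = (n_timepoints - width) // step + 1
    starts = tuple(i * step for i in range(n_steps))
    return WindowPlan(starts=starts, width_samples=width, step_samples=step)


@dataclass
class PatternMatrix:
    """Feature vectors for one condition in one analysis window.

    ``feature_layout`` maps feature position to ``(channel, time_offset)``
    with 1-based channel indices; the time offset is ``None`` for spatial
    features (which average over the window).
    ``runs`` records the run of origin of each exemplar (1-based).
    """

    vectors: np.ndarray  # (n_exemplars, n_features)
    labels: np.ndarray | None
    feature_layout: tuple[tuple[int, int | None], ...]
    runs: np.ndarray | None = None

    @property
    def n_exemplars(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_features(self) -> int:
        return self.vectors.shape[1]


def feature_layout(
    mode: str, n_channels: int, width: int, channel: int | None = None
) -> tuple[tuple[int, int | None], ...]:
    """Feature-position -> (channel, time-offset) map for a decoding mode."""
    if mode == "spatial":
        return tuple((ch, None) for ch in range(1, n_channels + 1))
    if mode == "temporal":
        return tuple((channel, t) for t in range(width))
    if mode == "spatiotemporal":
        return tuple(
            (ch, t) for ch in range(1, n_channels + 1) for t in range(width)
        )
    raise ConfigurationError(f"unknown mode '{mode}'")


def _window_features(
    block: np.ndarray, mode: str, channel0: int | None
) -> np.ndarray:
    """Vectorise one windowed block (width, channels, trials) -> (trials, F)."""
    if mode == "spatial":
        return block.mean(axis=0).T  # (trials, channels)
    if mode == "temporal":
        return block[:, channel0, :].T  # (trials, width)
    # spatiotemporal, channel-major: (trials, channels, width) -> flat
    return block.transpose(2, 1, 0).reshape(block.shape[2], -1)


def extract_patterns(
    dataset: EpochedDataset,
    start: int,
    width: int,
    mode: str,
    channel: int | None = None,
) -> dict[int, PatternMatrix]:
    """Extract per-condition pattern matrices for one analysis window.

    Trials are concatenated across runs in run order; run provenance is kept
    in ``PatternMatrix.runs`` so that block averaging and pooling can be done
    downstream. ``channel`` (1-based) is required for temporal mode and
    forbidden otherwise.
    """
    if mode == "temporal":
        if channel is None:
            raise ConfigurationError("temporal mode requires a channel index")
        if not 1 <= channel <= dataset.n_channels:
            raise ConditionLookupError(
                f"channel {channel} out of range 1..{dataset.n_channels}"
            )
    elif channel is not None:
        raise ConfigurationError(f"mode '{mode}' does not take a channel")
    if start < 0 or start + width > dataset.n_timepoints:
        raise ConfigurationError(
            f"window [{start}, {start + width}) outside epoch of "
            f"{dataset.n_timepoints} samples"
        )
    channel0 = channel - 1 if channel is not None else None
    layout = feature_layout(mode, dataset.n_channels, width, channel)
    out: dict[int, PatternMatrix] = {}
    for cond in dataset.conditions:
        chunks, runs, labels = [], [], []
        for run in dataset.runs:
            block = dataset.data[(run, cond)][start : start + width]
            feats = _window_features(block, mode, channel0)
            chunks.append(feats)
            runs.append(np.full(feats.shape[0], run, dtype=int))
            if dataset.svr_labels is not None and (run, cond) in dataset.svr_labels:
                labels.append(dataset.svr_labels[(run, cond)])
        out[cond] = PatternMatrix(
            vectors=np.vstack(chunks),
            labels=np.concatenate(labels) if labels else None,
            feature_layout=layout,
            runs=np.concatenate(runs),
        )
    return out
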