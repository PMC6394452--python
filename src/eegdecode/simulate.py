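"""Synthetic epoched-EEG generation with known ground truth.

The generator follows the validation design used throughout the test suite:
every sample of every epoch is independent Gaussian noise (mean 0, SD 1 by
default), and a "signal" dataset additionally carries a constant offset on
a chosen channel subset over a chosen timepoint range — e.g. a value of
0.05-0.3 added to the first 10 of 64 channels for timepoints 51-100 of a
100-timepoint epoch. Temporally independent noise is not typical of real
EEG; an optional AR(1) coefficient adds within-epoch temporal correlation
for stress tests but defaults off.

Channel and timepoint indices in :class:`SyntheticSpec` are 1-based and the
timepoint range is inclusive, matching the conventional description
"channels 1-10, timepoints 51-100".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import EpochedDataset
from .errors import ConfigurationError


@dataclass
class SyntheticSpec:
    """Parameters of the Gaussian-noise + additive-signal generator."""

    n_timepoints: int = 100
    n_channels: int = 64
    n_epochs: int = 1000
    noise_mean: float = 0.0
    noise_sd: float = 1.0
    signal_value: float = 0.0
    signal_channels: tuple[int, ...] = tuple(range(1, 11))
    signal_timepoints: tuple[int, int] = (51, 100)  # inclusive, 1-based
    n_runs: int = 1
    rng_seed: int = 0
    ar1_coefficient: float = 0.0
    sampling_rate_hz: float = 1000.0
    epoch_start_ms: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_timepoints, self.n_channels, self.n_epochs, self.n_runs) < 1:
            raise ConfigurationError("all dimensions must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        self.signal_channels = tuple(int(c) for c in self.signal_channels)
        if any(not 1 <= c <= self.n_channels for c in self.signal_channels):
            raise ConfigurationError(
                f"signal_channels {self.signal_channels} outside "
                f"1..{self.n_channels}"
            )
        lo, hi = (int(t) for t in self.signal_timepoints)
        if not (1 <= lo <= hi <= self.n_timepoints):
            raise ConfigurationError(
                f"signal_timepoints {self.signal_timepoints} outside "
                f"1..{self.n_timepoints}"
            )
        self.signal_timepoints = (lo, hi)
        if not -1 < self.ar1_coefficient < 1:
            raise ConfigurationError("ar1_coefficient must be in (-1, 1)")

    def replace(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)


def _noise_epochs(
    spec: SyntheticSpec, n_epochs: int, rng: np.random.Generator
) -> np.ndarray:
    """(timepoints, channels, epochs) i.i.d. Gaussian noise, optional AR(1)."""
    shape = (spec.n_timepoints, spec.n_channels, n_epochs)
    x = rng.normal(0.0, 1.0, size=shape)
    phi = spec.ar1_coefficient
    if phi != 0.0:
        # stationary AR(1) over the time axis with unit marginal variance
        innov_sd = np.sqrt(1.0 - phi**2)
        out = np.empty_like(x)
        out[0] = x[0]
        for t in range(1, spec.n_timepoints):
            out[t] = phi * out[t - 1] + innov_sd * x[t]
        x = out
    return spec.noise_mean + spec.noise_sd * x


def _add_signal(block: np.ndarray, spec: SyntheticSpec, value: float) -> None:
    if value == 0.0 or not spec.signal_channels:
        return
    lo, hi = spec.signal_timepoints
    ch_idx = np.asarray(spec.signal_channels) - 1
    block[lo - 1 : hi, ch_idx, :] += value


def _build_dataset(
    spec: SyntheticSpec, conditions: Sequence[float | None], seed: int
) -> EpochedDataset:
    """One dataset with one condition per entry; None = pure noise."""
    rng = np.random.default_rng(seed)
    per_run = spec.n_epochs // spec.n_runs
    counts = [
        per_run + (1 if r <= spec.n_epochs % spec.n_runs else 0)
        for r in range(1, spec.n_runs + 1)
    ]
    data = {}
    for r, n in zip(range(1, spec.n_runs + 1), counts):
        for c, value in enumerate(conditions, start=1):
            block = _noise_epochs(spec, n, rng)
            if value is not None:
                _add_signal(block, spec, value)
            data[(r, c)] = block
    return EpochedDataset(
        data=data,
        sampling_rate_hz=spec.sampling_rate_hz,
        epoch_start_ms=spec.epoch_start_ms,
    )


def generate_noise_dataset(spec: SyntheticSpec) -> EpochedDataset:
    """Single-condition dataset of pure i.i.d. Gaussian noise."""
    if spec.signal_value != 0.0:
        raise ConfigurationError(
            "generate_noise_dataset requires signal_value = 0; use "
            "generate_signal_dataset for signal datasets"
        )
    return _build_dataset(spec, [None], spec.rng_seed)


def generate_signal_dataset(spec: SyntheticSpec) -> EpochedDataset:
    """Single-condition dataset of noise plus the constant signal block.

    With ``signal_value = 0`` this is bit-identical to
    :func:`generate_noise_dataset` at the same seed.
    """
    return _build_dataset(spec, [spec.signal_value], spec.rng_seed)


def generate_multi_noise_dataset(
    spec: SyntheticSpec, n_conditions: int
) -> EpochedDataset:
    """Dataset of ``n_conditions`` independent pure-noise conditions.

    All conditions share the generator parameters and are statistically
    identical, so any decoding of their labels is chance by construction.
    """
    if n_conditions < 1:
        raise ConfigurationError("n_conditions must be >= 1")
    return _build_dataset(spec, [None] * n_conditions, spec.rng_seed)


def generate_two_condition_dataset(
    spec: SyntheticSpec, seed: int | None = None
) -> EpochedDataset:
    """Two-condition dataset: condition 1 noise, condition 2 noise + signal."""
    return _build_dataset(
        spec, [None, spec.signal_value],
        spec.rng_seed if seed is None else seed,
    )


def generate_group_study(
    spec: SyntheticSpec,
    n_subjects: int,
    heterogeneity: float = 0.0,
    seed_stride: int = 1000,
) -> list[EpochedDataset]:
    """Two-condition datasets for a simulated group study.

    Each subject gets an independent dataset from seed
    ``spec.rng_seed + i * seed_stride``; condition 1 is pure noise,
    condition 2 noise plus signal. ``heterogeneity`` is the fraction of
    subjects whose signal is silently set to 0 (taken from the end of the
    subject list), enabling ground-truth prevalence checks.
    """
    if n_subjects < 2:
        raise ConfigurationError("a group study needs >= 2 subjects")
    if not 0.0 <= heterogeneity <= 1.0:
        raise ConfigurationError("heterogeneity must be in [0, 1]")
    n_null = int(round(heterogeneity * n_subjects))
    out = []
    for i in range(n_subjects):
        value = 0.0 if i >= n_subjects - n_null else spec.signal_value
        out.append(
            _build_dataset(
                spec, [None, value], spec.rng_seed + i * seed_stride
            )
        )
    return out


def generate_svr_dataset(
    spec: SyntheticSpec, slope: float, label_range: tuple[float, float] = (-1.0, 1.0)
) -> EpochedDataset:
    """Single-condition dataset whose signal block scales with a trial label.

    Per-trial labels are drawn uniformly from ``label_range``; the amplitude
    added to the signal block of each trial is ``slope * label``, so windows
    covering the signal block carry label information and others do not.
    """
    if not np.isfinite(slope):
        raise ConfigurationError("slope must be finite")
    rng = np.random.default_rng(spec.rng_seed)
    per_run = spec.n_epochs // spec.n_runs
    counts = [
        per_run + (1 if r <= spec.n_epochs % spec.n_runs else 0)
        for r in range(1, spec.n_runs + 1)
    ]
    data, labels = {}, {}
    lo, hi = spec.signal_timepoints
    ch_idx = np.asarray(spec.signal_channels) - 1
    for r, n in zip(range(1, spec.n_runs + 1), counts):
        block = _noise_epochs(spec, n, rng)
        y = rng.uniform(label_range[0], label_range[1], size=n)
        if ch_idx.size:
            block[lo - 1 : hi, ch_idx, :] += slope * y[None, None, :]
        data[(r, 1)] = block
        labels[(r, 1)] = y
    return EpochedDataset(
        data=data,
        sampling_rate_hz=spec.sampling_rate_hz,
        epoch_start_ms=spec.epoch_start_ms,
        svr_labels=labels,
    )
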