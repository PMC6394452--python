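"""Epoched-data containers, configuration, and file I/O.

The central container is :class:`EpochedDataset`: a per-subject mapping from
``(run, condition)`` (1-based, as in the conventional MATLAB cell-array
export of epoched ERP data) to a 3-D amplitude array of shape
``(timepoints, channels, trials)`` in microvolts. Datasets can be read from
MATLAB MAT files (both the classic v7 format and the HDF5-backed v7.3
format) holding the ``eeg_sorted_cond{run, cond}`` cell-array layout, or
from a transparent native directory format (JSON manifest plus raw
little-endian float64 arrays).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import (
    ConditionLookupError,
    ConfigurationError,
    FormatError,
    ValidationError,
)

DEFAULT_MAT_VARIABLE = "eeg_sorted_cond"

_MANIFEST_NAME = "manifest.json"


def _as_3d(arr: np.ndarray) -> np.ndarray:
    """Coerce a (T, C) single-trial array to (T, C, 1)."""
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim == 2:
        a = a[:, :, np.newaxis]
    if a.ndim != 3:
        raise ValidationError(
            f"expected a 3-D (timepoints, channels, trials) array, got ndim={a.ndim}"
        )
    return a


@dataclass
class EpochedDataset:
    """Per-subject epoched EEG amplitudes organised by run and condition.

    Parameters
    ----------
    data
        Mapping ``(run, condition) -> array`` with 1-based, contiguous run and
        condition indices. Each array has shape
        ``(n_timepoints, n_channels, n_trials)``; timepoint and channel counts
        must agree across all cells.
    sampling_rate_hz
        Sampling rate of the epoched data in Hz.
    epoch_start_ms
        Time of the first sample relative to the time-locking event, in ms
        (negative for a pre-event baseline).
    channel_names
        Optional channel labels; length must equal ``n_channels``.
    svr_labels
        Optional per-trial continuous labels for support vector regression,
        keyed like ``data``; each entry must have one value per trial.
    """

    data: dict[tuple[int, int], np.ndarray]
    sampling_rate_hz: float = 1000.0
    epoch_start_ms: float = 0.0
    channel_names: list[str] | None = None
    svr_labels: dict[tuple[int, int], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.data = {
            (int(r), int(c)): _as_3d(a) for (r, c), a in self.data.items()
        }
        if self.svr_labels is not None:
            self.svr_labels = {
                (int(r), int(c)): np.asarray(v, dtype=np.float64).ravel()
                for (r, c), v in self.svr_labels.items()
            }
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def runs(self) -> list[int]:
        return sorted({r for r, _ in self.data})

    @property
    def conditions(self) -> list[int]:
        return sorted({c for _, c in self.data})

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_timepoints(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def n_channels(self) -> int:
        return next(iter(self.data.values())).shape[1]

    def n_trials(self, run: int, condition: int) -> int:
        return self.data[(run, condition)].shape[2]

    def validate(self) -> None:
        """Check all container invariants; raise ``ValidationError`` otherwise."""
        if not self.data:
            raise ValidationError("dataset contains no (run, condition) cells")
        runs, conds = self.runs, self.conditions
        if runs != list(range(1, len(runs) + 1)):
            raise ValidationError(f"run indices must be contiguous from 1, got {runs}")
        if conds != list(range(1, len(conds) + 1)):
            raise ValidationError(
                f"condition indices must be contiguous from 1, got {conds}"
            )
        missing = [
            (r, c) for r in runs for c in conds if (r, c) not in self.data
        ]
        if missing:
            raise ValidationError(f"missing (run, condition) cells: {missing}")
        ref_t, ref_c = None, None
        bad: list[str] = []
        for key in sorted(self.data):
            arr = self.data[key]
            t, c, n = arr.shape
            if n < 1:
                bad.append(f"(run {key[0]}, cond {key[1]}): zero trials")
                continue
            if ref_t is None:
                ref_t, ref_c = t, c
            elif (t, c) != (ref_t, ref_c):
                bad.append(
                    f"(run {key[0]}, cond {key[1]}): shape {t}x{c} differs "
                    f"from {ref_t}x{ref_c}"
                )
        if bad:
            raise ValidationError(
                "inconsistent cell dimensions: " + "; ".join(bad)
            )
        if self.channel_names is not None and len(self.channel_names) != ref_c:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {ref_c} channels"
            )
        if self.svr_labels is not None:
            for key, labels in self.svr_labels.items():
                if key not in self.data:
                    raise ValidationError(f"svr_labels has unknown cell {key}")
                if labels.size != self.data[key].shape[2]:
                    raise ValidationError(
                        f"svr_labels for (run {key[0]}, cond {key[1]}) has "
                        f"{labels.size} values for {self.data[key].shape[2]} trials"
                    )

    # -- operations --------------------------------------------------------

    def reduce_conditions(self, group: Sequence[int]) -> "EpochedDataset":
        """Return a copy containing only ``group``, re-indexed 1..len(group).

        The conditions keep the order given in ``group``; the source dataset
        is not modified.
        """
        group = tuple(int(g) for g in group)
        if not group:
            raise ConditionLookupError("empty condition group")
        known = set(self.conditions)
        unknown = [g for g in group if g not in known]
        if unknown:
            raise ConditionLookupError(
                f"unknown condition indices {unknown}; dataset has conditions "
                f"{self.conditions}"
            )
        data = {
            (r, new_c): self.data[(r, old_c)].copy()
            for r in self.runs
            for new_c, old_c in enumerate(group, start=1)
        }
        labels = None
        if self.svr_labels is not None:
            labels = {
                (r, new_c): self.svr_labels[(r, old_c)].copy()
                for r in self.runs
                for new_c, old_c in enumerate(group, start=1)
                if (r, old_c) in self.svr_labels
            }
        return EpochedDataset(
            data=data,
            sampling_rate_hz=self.sampling_rate_hz,
            epoch_start_ms=self.epoch_start_ms,
            channel_names=list(self.channel_names) if self.channel_names else None,
            svr_labels=labels or None,
        )

    def equals(self, other: "EpochedDataset") -> bool:
        """Element-wise equality of amplitudes, labels and metadata."""
        if sorted(self.data) != sorted(other.data):
            return False
        if any(
            not np.array_equal(self.data[k], other.data[k]) for k in self.data
        ):
            return False
        if (self.svr_labels is None) != (other.svr_labels is None):
            return False
        if self.svr_labels is not None:
            if sorted(self.svr_labels) != sorted(other.svr_labels):
                return False
            if any(
                not np.array_equal(self.svr_labels[k], other.svr_labels[k])
                for k in self.svr_labels
            ):
                return False
        return (
            self.sampling_rate_hz == other.sampling_rate_hz
            and self.epoch_start_ms == other.epoch_start_ms
            and self.channel_names == other.channel_names
        )

    def sample_times_ms(self) -> np.ndarray:
        """Time of each sample relative to the event, in ms."""
        step = 1000.0 / self.sampling_rate_hz
        return self.epoch_start_ms + step * np.arange(self.n_timepoints)


def reduce_conditions(dataset: EpochedDataset, group: Sequence[int]) -> EpochedDataset:
    """Functional alias for :meth:`EpochedDataset.reduce_conditions`."""
    return dataset.reduce_conditions(group)


# ---------------------------------------------------------------------------
# MAT I/O
# ---------------------------------------------------------------------------


def _load_mat_cells(path: Path, variable: str) -> np.ndarray:
    """Read a run x condition cell array from a v7 or v7.3 MAT file.

    Returns a 2-D object array indexed ``[run-1, cond-1]``.
    """
    import scipy.io

    try:
        mat = scipy.io.loadmat(path)
    except (NotImplementedError, ValueError):
        # v7.3 files are HDF5-backed; scipy cannot read them
        return _load_mat_cells_v73(path, variable)
    if variable not in mat:
        raise FormatError(
            f"MAT file {path} has no variable '{variable}'; "
            f"found {[k for k in mat if not k.startswith('__')]}"
        )
    cells = np.asarray(mat[variable])
    if cells.dtype != object:
        # a plain numeric array is treated as a single-cell layout
        cells_obj = np.empty((1, 1), dtype=object)
        cells_obj[0, 0] = cells
        cells = cells_obj
    if cells.ndim == 1:
        cells = cells.reshape(1, -1)
    return cells


def _load_mat_cells_v73(path: Path, variable: str) -> np.ndarray:
    import h5py

    with h5py.File(path, "r") as f:
        if variable not in f:
            raise FormatError(
                f"MAT v7.3 file {path} has no variable '{variable}'; "
                f"found {[k for k in f.keys() if not k.startswith('#')]}"
            )
        node = f[variable]
        if isinstance(node, h5py.Dataset) and node.dtype != h5py.ref_dtype:
            # plain numeric array; MATLAB stores column-major -> reverse axes
            arr = np.asarray(node).transpose()
            cells = np.empty((1, 1), dtype=object)
            cells[0, 0] = arr
            return cells
        refs = np.asarray(node)
        if refs.ndim == 1:
            refs = refs.reshape(-1, 1)
        # HDF5 stores the MATLAB {run, cond} cell array transposed
        n_cond, n_run = refs.shape
        cells = np.empty((n_run, n_cond), dtype=object)
        for ci in range(n_cond):
            for ri in range(n_run):
                cells[ri, ci] = np.asarray(f[refs[ci, ri]]).transpose()
        return cells


def load_mat_dataset(
    path: str | Path,
    variable: str = DEFAULT_MAT_VARIABLE,
    sampling_rate_hz: float = 1000.0,
    epoch_start_ms: float = 0.0,
    channel_names: list[str] | None = None,
    labels_path: str | Path | None = None,
    labels_variable: str | None = None,
) -> EpochedDataset:
    """Load the ``{run, cond}`` cell-array MAT layout into an ``EpochedDataset``.

    Both MAT v7 and v7.3 (HDF5) files are accepted. Sampling rate, epoch
    start, and channel names are not part of the MAT layout and are supplied
    by the caller. Optional per-trial regression labels are read from
    ``labels_path`` (``labels_variable`` names the cell/array variable; any
    single variable is accepted if the name is not given).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cells = _load_mat_cells(path, variable)
    if cells.size == 0:
        raise FormatError(f"variable '{variable}' in {path} is an empty cell array")
    data: dict[tuple[int, int], np.ndarray] = {}
    for ri in range(cells.shape[0]):
        for ci in range(cells.shape[1]):
            cell = cells[ri, ci]
            if cell is None or np.size(cell) == 0:
                raise FormatError(
                    f"empty cell at run {ri + 1}, condition {ci + 1} in {path}"
                )
            data[(ri + 1, ci + 1)] = _as_3d(np.asarray(cell, dtype=np.float64))
    svr_labels = None
    if labels_path is not None:
        svr_labels = _load_mat_labels(
            Path(labels_path), labels_variable, n_runs=cells.shape[0],
            n_conds=cells.shape[1],
        )
    return EpochedDataset(
        data=data,
        sampling_rate_hz=sampling_rate_hz,
        epoch_start_ms=epoch_start_ms,
        channel_names=channel_names,
        svr_labels=svr_labels,
    )


def _load_mat_labels(
    path: Path, variable: str | None, n_runs: int, n_conds: int
) -> dict[tuple[int, int], np.ndarray]:
    import scipy.io

    mat = scipy.io.loadmat(path)
    keys = [k for k in mat if not k.startswith("__")]
    if variable is None:
        if len(keys) != 1:
            raise FormatError(
                f"labels file {path} holds {len(keys)} variables {keys}; "
                "specify which one holds the labels"
            )
        variable = keys[0]
    if variable not in mat:
        raise FormatError(f"labels file {path} has no variable '{variable}'")
    raw = np.asarray(mat[variable])
    labels: dict[tuple[int, int], np.ndarray] = {}
    if raw.dtype == object:
        if raw.ndim == 1:
            raw = raw.reshape(1, -1)
        for ri in range(raw.shape[0]):
            for ci in range(raw.shape[1]):
                labels[(ri + 1, ci + 1)] = np.asarray(
                    raw[ri, ci], dtype=np.float64
                ).ravel()
    else:
        if n_runs != 1 or n_conds != 1:
            raise FormatError(
                "plain-array labels are only valid for a single-run, "
                "single-condition dataset"
            )
        labels[(1, 1)] = raw.astype(np.float64).ravel()
    return labels


def save_mat_dataset(
    dataset: EpochedDataset,
    path: str | Path,
    variable: str = DEFAULT_MAT_VARIABLE,
) -> None:
    """Write the dataset as a classic (v5/v7-compatible) MAT cell array."""
    import scipy.io

    cells = np.empty((dataset.n_runs, dataset.n_conditions), dtype=object)
    for r in dataset.runs:
        for c in dataset.conditions:
            cells[r - 1, c - 1] = dataset.data[(r, c)]
    scipy.io.savemat(Path(path), {variable: cells})


# ---------------------------------------------------------------------------
# Native container: JSON manifest + raw little-endian float64 arrays
# ---------------------------------------------------------------------------


def save_native(dataset: EpochedDataset, path: str | Path) -> None:
    """Write a dataset as a directory with a JSON manifest and raw arrays.

    Each (run, condition) cell is one ``run{r}_cond{c}.f64`` file of
    little-endian float64 values in C order with shape recorded in the
    manifest; the layout diffs cleanly and supports partial loading.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    cells = {}
    for (r, c), arr in sorted(dataset.data.items()):
        fname = f"run{r}_cond{c}.f64"
        arr.astype("<f8").tofile(root / fname)
        cells[f"{r},{c}"] = {"file": fname, "shape": list(arr.shape)}
    manifest = {
        "format": "eegdecode-native",
        "version": 1,
        "sampling_rate_hz": dataset.sampling_rate_hz,
        "epoch_start_ms": dataset.epoch_start_ms,
        "channel_names": dataset.channel_names,
        "cells": cells,
        "svr_labels": (
            {f"{r},{c}": v.tolist() for (r, c), v in dataset.svr_labels.items()}
            if dataset.svr_labels is not None
            else None
        ),
    }
    (root / _MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))


def load_native(path: str | Path) -> EpochedDataset:
    """Load a dataset written by :func:`save_native`."""
    root = Path(path)
    manifest_path = root / _MANIFEST_NAME
    if not manifest_path.exists():
        raise FormatError(f"{root} has no {_MANIFEST_NAME}; not a native container")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format") != "eegdecode-native":
        raise FormatError(f"{manifest_path} is not an eegdecode-native manifest")
    data = {}
    for key, entry in manifest["cells"].items():
        r, c = (int(x) for x in key.split(","))
        arr = np.fromfile(root / entry["file"], dtype="<f8")
        data[(r, c)] = arr.reshape(entry["shape"])
    svr_labels = None
    if manifest.get("svr_labels"):
        svr_labels = {
            tuple(int(x) for x in key.split(",")): np.asarray(v, dtype=np.float64)
            for key, v in manifest["svr_labels"].items()
        }
    return EpochedDataset(
        data=data,
        sampling_rate_hz=manifest["sampling_rate_hz"],
        epoch_start_ms=manifest["epoch_start_ms"],
        channel_names=manifest["channel_names"],
        svr_labels=svr_labels,
    )


# ---------------------------------------------------------------------------
# Decoding configuration
# ---------------------------------------------------------------------------

MODES = ("spatial", "temporal", "spatiotemporal")
ANALYSIS_TYPES = ("classification", "regression", "cross_condition")


def ms_to_samples(value_ms: float, sampling_rate_hz: float, what: str) -> int:
    """Convert a duration in ms to samples; non-integral results are an error.

    Silent rounding would quietly change the analysis grid, so a window or
    step width that does not correspond to a whole number of samples is
    rejected.
    """
    exact = value_ms * sampling_rate_hz / 1000.0
    rounded = round(exact)
    if abs(exact - rounded) > 1e-9:
        raise ConfigurationError(
            f"{what} of {value_ms} ms is {exact} samples at "
            f"{sampling_rate_hz} Hz; must be a whole number of samples"
        )
    if rounded < 1:
        raise ConfigurationError(f"{what} must be at least one sample")
    return int(rounded)


@dataclass
class DecodingConfig:
    """All parameters of a per-subject decoding analysis.

    Defaults follow common practice for linear decoding of ERP amplitude
    patterns: 10-fold cross-validation repeated over 10 independent set
    draws, a linear soft-margin SVM with C = 1 for classification and a
    linear SVR with C = 0.1 for regression.
    """

    mode: str = "spatial"
    analysis_type: str = "classification"
    window_width_ms: float = 10.0
    step_ms: float = 10.0
    k_folds: int = 10
    m_repetitions: int = 10
    average_by_block: bool = False
    svm_cost: float | None = None
    permute_labels: bool = False
    rng_seed: int = 0
    discrimination_groups: list[tuple[int, ...]] = field(
        default_factory=lambda: [(1, 2)]
    )
    channel: int | None = None
    zscore_features: bool = False
    backend_factory: Callable[..., object] | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode '{self.mode}'; choose from {MODES}")
        if self.analysis_type not in ANALYSIS_TYPES:
            raise ConfigurationError(
                f"unknown analysis_type '{self.analysis_type}'; "
                f"choose from {ANALYSIS_TYPES}"
            )
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be >= 2")
        if self.m_repetitions < 1:
            raise ConfigurationError("m_repetitions must be >= 1")
        if self.window_width_ms <= 0 or self.step_ms <= 0:
            raise ConfigurationError("window_width_ms and step_ms must be positive")
        if self.svm_cost is not None and self.svm_cost <= 0:
            raise ConfigurationError("svm_cost must be positive")
        if self.mode == "temporal" and self.channel is None:
            raise ConfigurationError("temporal mode requires a channel index")
        if self.mode != "temporal" and self.channel is not None:
            raise ConfigurationError(
                f"channel is only meaningful in temporal mode, not '{self.mode}'"
            )
        self.discrimination_groups = [
            tuple(int(c) for c in g) for g in self.discrimination_groups
        ]
        if self.analysis_type == "cross_condition":
            if len(self.discrimination_groups) != 2:
                raise ConfigurationError(
                    "cross_condition needs exactly two discrimination groups "
                    "(train-context, test-context)"
                )
            a, b = self.discrimination_groups
            if len(a) != len(b):
                raise ConfigurationError(
                    "train and test contexts must have equal class counts"
                )
            if set(a) & set(b):
                raise ConfigurationError(
                    f"train and test contexts overlap: {sorted(set(a) & set(b))}"
                )

    @property
    def effective_cost(self) -> float:
        if self.svm_cost is not None:
            return self.svm_cost
        return 0.1 if self.analysis_type == "regression" else 1.0

    def window_width_samples(self, sampling_rate_hz: float) -> int:
        return ms_to_samples(self.window_width_ms, sampling_rate_hz, "window width")

    def step_samples(self, sampling_rate_hz: float) -> int:
        return ms_to_samples(self.step_ms, sampling_rate_hz, "step size")

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "analysis_type": self.analysis_type,
            "window_width_ms": self.window_width_ms,
            "step_ms": self.step_ms,
            "k_folds": self.k_folds,
            "m_repetitions": self.m_repetitions,
            "average_by_block": self.average_by_block,
            "svm_cost": self.svm_cost,
            "permute_labels": self.permute_labels,
            "rng_seed": self.rng_seed,
            "discrimination_groups": [list(g) for g in self.discrimination_groups],
            "channel": self.channel,
            "zscore_features": self.zscore_features,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DecodingConfig":
        d = dict(d)
        d.pop("backend_factory", None)
        groups = d.get("discrimination_groups")
        if groups is not None:
            d["discrimination_groups"] = [tuple(g) for g in groups]
        return cls(**d)

    def replace(self, **kwargs) -> "DecodingConfig":
        return replace(self, **kwargs)
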