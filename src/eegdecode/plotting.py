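"""Result figures: accuracy time courses and channel maps.

Time-course plots show group (or single-subject) accuracy per analysis
window, with the x-axis in ms derived from the epoch start and sampling
rate, optional standard-error bars, the permuted-label trace, a chance
reference line, and shading of significant windows. Channel maps display
per-channel values; without electrode coordinates they degrade to an
ordered bar strip, with coordinates they become a simple 2-D scatter heat
map (no scalp interpolation).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import ConfigurationError

SUPPORTED_FORMATS = (".png", ".pdf", ".tiff", ".tif", ".eps", ".jpg", ".svg")


def _check_format(path: Path) -> None:
    if path.suffix.lower() not in SUPPORTED_FORMATS:
        raise ConfigurationError(
            f"unknown figure format '{path.suffix}'; supported: "
            f"{', '.join(SUPPORTED_FORMATS)}"
        )


def plot_time_course(
    result,
    path: str | Path,
    chance: float | None = 50.0,
    title: str | None = None,
    ylabel: str = "decoding accuracy (%)",
) -> Path:
    """Plot an accuracy information time course to a figure file.

    ``result`` is a :class:`~eegdecode.group.GroupResult` or
    :class:`~eegdecode.decoding.DecodingResult`; group results get
    standard-error bars and significance shading, and both draw the
    permuted-label trace when present.
    """
    path = Path(path)
    _check_format(path)
    times = np.asarray(result.window_times_ms, dtype=float)
    centers = times.mean(axis=1)
    fig, ax = plt.subplots(figsize=(7, 4))
    subject_matrix = getattr(result, "subject_matrix", None)
    if subject_matrix is not None:
        mean = subject_matrix.mean(axis=0)
        se = subject_matrix.std(axis=0, ddof=1) / np.sqrt(subject_matrix.shape[0])
        ax.errorbar(centers, mean, yerr=se, color="k", lw=1.5, capsize=2,
                    label="observed")
        perm = result.permuted_matrix
        if perm is not None:
            ax.errorbar(
                centers, perm.mean(axis=0),
                yerr=perm.std(axis=0, ddof=1) / np.sqrt(perm.shape[0]),
                color="tab:blue", lw=1.2, capsize=2, label="permuted labels",
            )
        mask = getattr(result, "significant_mask", None)
        if mask is not None and mask.any():
            for s in np.flatnonzero(mask):
                ax.axvspan(times[s, 0], times[s, 1], color="0.85", zorder=0)
    else:
        ax.plot(centers, result.accuracy, color="k", lw=1.5, label="observed")
        if getattr(result, "permuted_accuracy", None) is not None:
            ax.plot(centers, result.permuted_accuracy, color="tab:blue",
                    lw=1.2, label="permuted labels")
        chance = result.chance_level if chance == 50.0 else chance
    if chance is not None:
        ax.axhline(chance, color="0.5", ls="--", lw=1, label="chance")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_channel_map(
    values: Sequence[float],
    path: str | Path,
    channel_names: Sequence[str] | None = None,
    coordinates: Mapping[str, tuple[float, float]] | None = None,
    title: str | None = None,
    cbar_label: str = "value",
) -> Path:
    """Plot per-channel values as a bar strip or, with coordinates, a 2-D map.

    ``coordinates`` maps channel name -> (x, y) positions (e.g. flattened
    10-20 locations). Without coordinates the channels are shown in order as
    a colour-coded bar strip.
    """
    path = Path(path)
    _check_format(path)
    values = np.asarray(values, dtype=float)
    n = values.size
    names = list(channel_names) if channel_names else [str(i + 1) for i in range(n)]
    fig, ax = plt.subplots(figsize=(7, 4))
    if coordinates:
        missing = [nm for nm in names if nm not in coordinates]
        if missing:
            raise ConfigurationError(
                f"no coordinates for channels {missing[:5]}..."
            )
        xy = np.array([coordinates[nm] for nm in names], dtype=float)
        sc = ax.scatter(xy[:, 0], xy[:, 1], c=values, s=160, cmap="viridis")
        for nm, (x, y) in zip(names, xy):
            ax.annotate(nm, (x, y), fontsize=6, ha="center", va="center")
        ax.set_aspect("equal")
        ax.set_xticks([])
        ax.set_yticks([])
        fig.colorbar(sc, ax=ax, label=cbar_label)
    else:
        cmap = plt.get_cmap("viridis")
        vmin, vmax = values.min(), values.max()
        span = (vmax - vmin) or 1.0
        ax.bar(np.arange(1, n + 1), values,
               color=cmap((values - vmin) / span))
        ax.set_xlabel("channel")
        ax.set_ylabel(cbar_label)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
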