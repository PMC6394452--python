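"""Group-level inference on decoding performance and feature weights.

Subjects' window-wise mean accuracies form a ``(n_subjects, n_steps)``
matrix. Each analysis window is tested against chance — either the
theoretical level (50% for two balanced classes, 100/c in general) or each
subject's own mean permuted-label accuracy — with a paired Student t-test
or Yuen's robust paired t-test on trimmed means. Because one test is run
per window, the resulting p-values are corrected for multiple comparisons
by one of: Holm-Bonferroni, maximum-statistic or cluster-based sign-flip
permutation tests, generalised family-wise error control permitting ``u``
false positives, or false discovery rate control (Benjamini-Hochberg and
its two-stage adaptive variant).

Note that above-chance group decoding supports a fixed-effects claim (some
individuals carry decodable information), not a population mean claim. The
minimum-statistic prevalence test additionally yields a lower bound on the
population fraction of subjects with decodable information.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .decoding import DecodingResult
from .errors import ConfigurationError, ValidationError

TESTS = ("student_paired", "yuen_paired")
CORRECTIONS = ("none", "holm", "max_perm", "cluster_perm", "gfwer_korn",
               "fdr_bh", "fdr_bky")


# ---------------------------------------------------------------------------
# Paired tests against chance
# ---------------------------------------------------------------------------


def _student_one_sample(diffs: np.ndarray, tail: str) -> tuple[float, float]:
    n = diffs.size
    sd = diffs.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance of differences; p set to 1", stacklevel=3)
        return 0.0, 1.0
    t = diffs.mean() / (sd / math.sqrt(n))
    return t, _t_pvalue(t, n - 1, tail)


def _t_pvalue(t: float, df: float, tail: str) -> float:
    if tail == "greater":
        return float(stats.t.sf(t, df))
    if tail == "less":
        return float(stats.t.cdf(t, df))
    return float(2 * stats.t.sf(abs(t), df))


def trimmed_mean(x: np.ndarray, trim: float) -> float:
    return float(stats.trim_mean(x, trim))


def winsorized_variance(x: np.ndarray, trim: float) -> float:
    """Sample variance (ddof=1) of the winsorised values."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    g = int(np.floor(trim * n))
    w = xs.copy()
    w[:g] = xs[g]
    w[n - g :] = xs[n - g - 1]
    return float(w.var(ddof=1))


def _yuen_one_sample(
    diffs: np.ndarray, trim: float, tail: str
) -> tuple[float, float]:
    """Yuen's trimmed-means paired test on difference scores.

    Paired-difference form of the trimmed t: the trimmed mean of the
    differences over the winsorised standard error
    ``sqrt(s_w^2 (n-1) / (h (h-1)))`` with ``h = n - 2 floor(trim n)``
    effective observations and ``h - 1`` degrees of freedom.
    """
    n = diffs.size
    g = int(np.floor(trim * n))
    h = n - 2 * g
    if h < 2:
        raise ConfigurationError(
            f"trim proportion {trim} leaves {h} effective observations of {n}"
        )
    sw2 = winsorized_variance(diffs, trim)
    if sw2 == 0:
        warnings.warn(
            "zero winsorised variance of differences; p set to 1", stacklevel=3
        )
        return 0.0, 1.0
    se = math.sqrt(sw2 * (n - 1) / (h * (h - 1)))
    t = trimmed_mean(diffs, trim) / se
    return t, _t_pvalue(t, h - 1, tail)


def test_vs_chance(
    subject_matrix: np.ndarray,
    chance: float | np.ndarray,
    test: str = "student_paired",
    tail: str = "greater",
    trim: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window paired comparison of subject accuracies against chance.

    ``chance`` is either the theoretical level (scalar) or a matrix of each
    subject's mean permuted-label accuracy (same shape as
    ``subject_matrix``). Returns per-window ``(t_stats, p_values)``. The
    default tail is one-sided: above-chance decoding is the hypothesis.
    """
    X = np.atleast_2d(np.asarray(subject_matrix, dtype=float))
    n_subj, n_steps = X.shape
    if n_subj < 3:
        raise ConfigurationError("group testing needs at least 3 subjects")
    ref = np.asarray(chance, dtype=float)
    if ref.ndim == 0:
        ref = np.full_like(X, float(ref))
    if ref.shape != X.shape:
        raise ValidationError(
            f"chance reference shape {ref.shape} does not match subject "
            f"matrix {X.shape}"
        )
    if test not in TESTS:
        raise ConfigurationError(f"unknown test '{test}'; choose from {TESTS}")
    diffs = X - ref
    t_stats = np.empty(n_steps)
    p_values = np.empty(n_steps)
    for s in range(n_steps):
        if test == "student_paired":
            t_stats[s], p_values[s] = _student_one_sample(diffs[:, s], tail)
        else:
            t_stats[s], p_values[s] = _yuen_one_sample(diffs[:, s], trim, tail)
    return t_stats, p_values


# ---------------------------------------------------------------------------
# Multiple-comparison corrections
# ---------------------------------------------------------------------------


def _signflip_t_matrix(
    diffs: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Null t-statistics per step under random within-subject sign flips.

    Returns an ``(n_permutations, n_steps)`` matrix; the observed (unflipped)
    labelling is always included as the first permutation.
    """
    n_subj, n_steps = diffs.shape
    signs = rng.choice((-1.0, 1.0), size=(n_permutations, n_subj))
    signs[0] = 1.0  # observed labelling is permutation 0
    flipped = signs[:, :, None] * diffs[None, :, :]  # (B, n_subj, n_steps)
    mean = flipped.mean(axis=1)
    sd = flipped.std(axis=1, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)
    return mean / (sd / math.sqrt(n_subj))


def _clusters(mask: np.ndarray) -> list[np.ndarray]:
    """Runs of True in a 1-D boolean mask, as index arrays."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    return np.split(idx, breaks + 1)


def _max_cluster_mass(t_row: np.ndarray, thresh: float) -> float:
    """Largest absolute summed-t mass of suprathreshold clusters (signed runs)."""
    best = 0.0
    for sign in (1.0, -1.0):
        for cluster in _clusters(sign * t_row > thresh):
            best = max(best, abs(t_row[cluster].sum()))
    return best


@dataclass
class CorrectionResult:
    """Outcome of a multiple-comparison correction across analysis windows."""

    significant_mask: np.ndarray
    adjusted_p: np.ndarray | None
    method: str
    alpha: float
    details: dict = field(default_factory=dict)


def correct_multiple(
    p_values: np.ndarray | None,
    method: str,
    alpha: float = 0.05,
    diffs: np.ndarray | None = None,
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = None,
    tail: str = "greater",
    cluster_alpha: float = 0.05,
    u_false_positives: int = 1,
) -> CorrectionResult:
    """Apply one multiple-comparison correction over analysis windows.

    ``holm``, ``fdr_bh`` and ``fdr_bky`` operate on ``p_values``; the
    permutation methods (``max_perm``, ``cluster_perm``, ``gfwer_korn``)
    resample within-subject sign flips of the difference scores ``diffs``
    (``(n_subjects, n_steps)``, real minus chance reference). Cluster
    correction treats temporally adjacent windows exceeding the
    cluster-forming threshold (uncorrected two-sided p < ``cluster_alpha``)
    as one cluster with mass equal to the summed t statistic.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    if method not in CORRECTIONS:
        raise ConfigurationError(
            f"unknown correction '{method}'; choose from {CORRECTIONS}"
        )
    if method in ("holm", "fdr_bh", "fdr_bky", "none"):
        if p_values is None:
            raise ConfigurationError(f"method '{method}' needs p-values")
        p = np.asarray(p_values, dtype=float)
        if method == "none":
            return CorrectionResult(p <= alpha, p, method, alpha)
        from statsmodels.stats.multitest import multipletests

        sm_name = {"holm": "holm", "fdr_bh": "fdr_bh", "fdr_bky": "fdr_tsbky"}
        reject, p_adj, _, _ = multipletests(p, alpha=alpha, method=sm_name[method])
        return CorrectionResult(reject, p_adj, method, alpha)

    # permutation-based methods
    if diffs is None:
        raise ConfigurationError(
            f"method '{method}' needs per-subject difference scores"
        )
    if n_permutations < 100:
        warnings.warn(
            f"{n_permutations} permutations give a coarse null; >= 100 "
            "recommended",
            stacklevel=2,
        )
    rng = np.random.default_rng(rng)
    diffs = np.asarray(diffs, dtype=float)
    n_subj, n_steps = diffs.shape
    t_null = _signflip_t_matrix(diffs, n_permutations, rng)
    t_obs = t_null[0]
    stat_null = t_null if tail == "greater" else np.abs(t_null)
    stat_obs = stat_null[0]

    if method == "max_perm":
        max_null = stat_null.max(axis=1)
        p_adj = (max_null[:, None] >= stat_obs[None, :]).mean(axis=0)
        return CorrectionResult(p_adj <= alpha, p_adj, method, alpha,
                                details={"max_null": max_null})

    if method == "gfwer_korn":
        # single-step control of P(> u false positives): threshold at the
        # (1 - alpha) quantile of the (u+1)-th largest null statistic
        u = int(u_false_positives)
        if u >= n_steps:
            raise ConfigurationError(
                f"u={u} false positives with only {n_steps} windows"
            )
        order_null = np.sort(stat_null, axis=1)[:, n_steps - 1 - u]
        p_adj = (order_null[:, None] >= stat_obs[None, :]).mean(axis=0)
        return CorrectionResult(p_adj <= alpha, p_adj, method, alpha,
                                details={"u": u})

    # cluster_perm
    if n_steps < 2:
        raise ConfigurationError("cluster correction needs >= 2 adjacent windows")
    df = n_subj - 1
    t_thresh = float(stats.t.ppf(1 - cluster_alpha / 2, df))
    null_mass = np.array(
        [_max_cluster_mass(t_null[b], t_thresh) for b in range(n_permutations)]
    )
    mask = np.zeros(n_steps, dtype=bool)
    cluster_ps: list[tuple[list[int], float]] = []
    sign_dirs = (1.0,) if tail == "greater" else (1.0, -1.0)
    for sign in sign_dirs:
        for cluster in _clusters(sign * t_obs > t_thresh):
            mass = abs(t_obs[cluster].sum())
            p_cl = float((null_mass >= mass).mean())
            cluster_ps.append((cluster.tolist(), p_cl))
            if p_cl <= alpha:
                mask[cluster] = True
    return CorrectionResult(mask, None, method, alpha,
                            details={"clusters": cluster_ps,
                                     "t_threshold": t_thresh})


# ---------------------------------------------------------------------------
# Prevalence inference (minimum statistic)
# ---------------------------------------------------------------------------


def prevalence_minimum_statistic(
    subject_real: np.ndarray,
    subject_perms: np.ndarray,
    alpha: float = 0.05,
    n_second_level: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-statistic global-null test and prevalence lower bound.

    Parameters
    ----------
    subject_real
        Observed accuracies, shape ``(n_subjects, n_steps)`` (or
        ``(n_subjects,)`` for one window).
    subject_perms
        First-level permutation accuracies per subject, shape
        ``(n_subjects, n_perms)`` or ``(n_subjects, n_perms, n_steps)``.
        The observed value is added as one more first-level permutation
        (the standard construction).
    alpha
        Level for the prevalence bound.
    n_second_level
        Monte-Carlo draws at the second level; the all-observed combination
        is always counted in its own null, so p >= 1/(n_second_level + 1).

    Returns
    -------
    (global_null_p, prevalence_lower_bound), each of length ``n_steps``.
    The bound is the largest majority fraction ``gamma`` whose null
    ``[ (1-gamma) p^(1/N) + gamma ]^N <= alpha`` is rejected, i.e.
    ``gamma* = (alpha^(1/N) - p^(1/N)) / (1 - p^(1/N))`` clipped to [0, 1].
    """
    real = np.asarray(subject_real, dtype=float)
    if real.ndim == 1:
        real = real[:, None]
    perms = np.asarray(subject_perms, dtype=float)
    if perms.ndim == 2:
        perms = perms[:, :, None]
    n_subj, n_perm, n_steps = perms.shape
    if real.shape != (n_subj, n_steps):
        raise ValidationError(
            f"real accuracies {real.shape} do not match permutations "
            f"{perms.shape}"
        )
    if n_perm < 2:
        raise ConfigurationError(
            "each subject needs >= 2 first-level permutation values"
        )
    min_achievable = (1.0 / (n_perm + 1)) ** 1  # per-subject resolution
    if min_achievable**n_subj > alpha and (1.0 / (n_second_level + 1)) > alpha:
        raise ConfigurationError(
            f"{n_perm} first-level permutations cannot resolve alpha={alpha}; "
            f"need at least {math.ceil(1 / alpha) - 1}"
        )
    rng = np.random.default_rng(rng)
    # first-level pool: observed value included as permutation 0
    pool = np.concatenate([real[:, None, :], perms], axis=1)  # (N, P+1, S)
    obs_min = real.min(axis=0)  # (S,)
    draws = rng.integers(0, n_perm + 1, size=(n_second_level, n_subj))
    count = np.zeros(n_steps, dtype=int)
    # vectorise over second-level draws per step
    for s in range(n_steps):
        vals = pool[np.arange(n_subj)[None, :], draws, s]  # (B, N)
        count[s] = int((vals.min(axis=1) >= obs_min[s]).sum())
    p_global = (count + 1) / (n_second_level + 1)
    N = n_subj
    p_root = p_global ** (1.0 / N)
    a_root = alpha ** (1.0 / N)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = (a_root - p_root) / (1.0 - p_root)
    gamma = np.where(p_global > alpha, 0.0, np.clip(gamma, 0.0, 1.0))
    return p_global, gamma


# ---------------------------------------------------------------------------
# Group feature weights
# ---------------------------------------------------------------------------


def group_feature_weights(
    per_subject_maps: Sequence[np.ndarray],
    steps: Sequence[int],
    alpha: float = 0.05,
    correction: str = "holm",
    test: str = "student_paired",
    tail: str = "greater",
    trim: float = 0.2,
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = None,
):
    """Channel-level group test of absolute, z-standardised feature weights.

    Each subject contributes a ``(n_steps, n_channels)`` per-channel weight
    map; the maps are averaged over the requested analysis windows and each
    channel's subject values are tested against zero (one-sample), corrected
    across channels.

    Returns a pandas DataFrame with per-channel mean, t, p and significance.
    """
    import pandas as pd

    if not steps:
        raise ConfigurationError("steps-to-average list must be non-empty")
    maps = [np.asarray(m, dtype=float) for m in per_subject_maps]
    n_channels = maps[0].shape[1]
    if any(m.shape[1] != n_channels for m in maps):
        raise ValidationError("subjects differ in channel count")
    steps = list(steps)
    X = np.vstack([m[steps].mean(axis=0) for m in maps])  # (n_subj, n_channels)
    t_stats, p_values = test_vs_chance(X, 0.0, test=test, tail=tail, trim=trim)
    corr = correct_multiple(
        p_values,
        correction,
        alpha=alpha,
        diffs=X,
        n_permutations=n_permutations,
        rng=rng,
        tail=tail,
    )
    return pd.DataFrame(
        {
            "channel": np.arange(1, n_channels + 1),
            "mean_weight_z": X.mean(axis=0),
            "t": t_stats,
            "p": p_values,
            "significant": corr.significant_mask,
        }
    )


# ---------------------------------------------------------------------------
# Group model / results objects
# ---------------------------------------------------------------------------


@dataclass
class GroupResult:
    """Group-level inference across analysis windows.

    ``subject_matrix`` holds each subject's window-wise mean accuracy;
    ``permuted_matrix`` the subject-mean permuted-label accuracies where
    available. Significance is reported after the chosen correction;
    prevalence fields are filled only when the minimum-statistic method ran.
    """

    subject_matrix: np.ndarray
    permuted_matrix: np.ndarray | None
    chance_reference: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    significant_mask: np.ndarray
    adjusted_p: np.ndarray | None
    window_times_ms: np.ndarray
    method_echo: dict
    prevalence_global_p: np.ndarray | None = None
    prevalence_lower_bound: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return self.subject_matrix.shape[0]

    @property
    def n_steps(self) -> int:
        return self.subject_matrix.shape[1]

    def summary(self):
        """Per-window summary table (pandas DataFrame)."""
        import pandas as pd

        mean = self.subject_matrix.mean(axis=0)
        se = self.subject_matrix.std(axis=0, ddof=1) / math.sqrt(self.n_subjects)
        d = {
            "window_start_ms": self.window_times_ms[:, 0],
            "window_end_ms": self.window_times_ms[:, 1],
            "mean_accuracy": mean,
            "se": se,
            "t": self.t_stats,
            "p": self.p_values,
            "significant": self.significant_mask,
        }
        if self.permuted_matrix is not None:
            d["mean_permuted"] = self.permuted_matrix.mean(axis=0)
        if self.prevalence_lower_bound is not None:
            d["prevalence_global_p"] = self.prevalence_global_p
            d["prevalence_lower_bound"] = self.prevalence_lower_bound
        return pd.DataFrame(d)

    def to_csv(self, path: str | Path) -> None:
        self.summary().to_csv(Path(path), index=False)


class GroupAnalysis:
    """Group-level model over per-subject decoding results.

    Built either from a list of :class:`~eegdecode.decoding.DecodingResult`
    or directly from accuracy matrices. ``fit()`` runs the chosen test and
    correction and returns a :class:`GroupResult`.

    Parameters
    ----------
    results
        Per-subject decoding results (all sharing the window grid), or None
        when matrices are given directly.
    subject_matrix, permuted_matrix, window_times_ms
        Direct-matrix alternative to ``results``.
    """

    def __init__(
        self,
        results: Sequence[DecodingResult] | None = None,
        subject_matrix: np.ndarray | None = None,
        permuted_matrix: np.ndarray | None = None,
        window_times_ms: np.ndarray | None = None,
        chance_level: float | None = None,
    ):
        if results is not None:
            if len(results) < 3:
                raise ConfigurationError("group analysis needs >= 3 subjects")
            steps = {r.n_steps for r in results}
            if len(steps) > 1:
                raise ValidationError(
                    f"subjects differ in window count: {sorted(steps)}"
                )
            self.subject_matrix = np.vstack([r.accuracy for r in results])
            perms = [r.permuted_accuracy for r in results]
            self.permuted_matrix = (
                np.vstack(perms) if all(p is not None for p in perms) else None
            )
            self.window_times_ms = results[0].window_times_ms
            self.chance_level = chance_level
            if self.chance_level is None:
                self.chance_level = results[0].chance_level
            self.results = list(results)
        else:
            if subject_matrix is None:
                raise ConfigurationError(
                    "provide per-subject results or a subject matrix"
                )
            self.subject_matrix = np.atleast_2d(
                np.asarray(subject_matrix, dtype=float)
            )
            if self.subject_matrix.shape[0] < 3:
                raise ConfigurationError("group analysis needs >= 3 subjects")
            self.permuted_matrix = (
                np.atleast_2d(np.asarray(permuted_matrix, dtype=float))
                if permuted_matrix is not None
                else None
            )
            n_steps = self.subject_matrix.shape[1]
            self.window_times_ms = (
                np.asarray(window_times_ms, dtype=float)
                if window_times_ms is not None
                else np.column_stack(
                    [np.arange(n_steps), np.arange(1, n_steps + 1)]
                ).astype(float)
            )
            self.chance_level = chance_level
            self.results = None

    def fit(
        self,
        test: str = "student_paired",
        correction: str = "holm",
        chance: str = "empirical",
        alpha: float = 0.05,
        tail: str = "greater",
        trim: float = 0.2,
        n_permutations: int = 1000,
        prevalence: bool = False,
        n_second_level: int = 10000,
        rng: np.random.Generator | int | None = None,
    ) -> GroupResult:
        """Run group inference and return a :class:`GroupResult`.

        ``chance='empirical'`` compares each subject against their own mean
        permuted-label accuracy (requires permuted results);
        ``chance='theoretical'`` uses the constant chance level. With
        ``prevalence=True`` the minimum-statistic global-null test and
        prevalence lower bound are additionally computed from the stored
        per-subject permutation distributions.
        """
        if chance == "empirical":
            if self.permuted_matrix is None:
                raise ConfigurationError(
                    "empirical chance requires permuted-label results; "
                    "run decoding with permute_labels=True or use "
                    "chance='theoretical'"
                )
            ref = self.permuted_matrix
        elif chance == "theoretical":
            if self.chance_level is None:
                raise ConfigurationError(
                    "no theoretical chance level known; pass chance_level"
                )
            ref = np.full_like(self.subject_matrix, self.chance_level)
        else:
            raise ConfigurationError(
                "chance must be 'empirical' or 'theoretical'"
            )
        t_stats, p_values = test_vs_chance(
            self.subject_matrix, ref, test=test, tail=tail, trim=trim
        )
        corr = correct_multiple(
            p_values,
            correction,
            alpha=alpha,
            diffs=self.subject_matrix - ref,
            n_permutations=n_permutations,
            rng=rng,
            tail=tail,
        )
        prev_p = prev_bound = None
        if prevalence:
            prev_p, prev_bound = self._prevalence(
                alpha=alpha, n_second_level=n_second_level, rng=rng
            )
        return GroupResult(
            subject_matrix=self.subject_matrix,
            permuted_matrix=self.permuted_matrix,
            chance_reference=ref,
            t_stats=t_stats,
            p_values=p_values,
            significant_mask=corr.significant_mask,
            adjusted_p=corr.adjusted_p,
            window_times_ms=self.window_times_ms,
            method_echo={
                "test": test,
                "correction": correction,
                "chance": chance,
                "alpha": alpha,
                "tail": tail,
                "trim": trim,
                "n_permutations": n_permutations,
            },
            prevalence_global_p=prev_p,
            prevalence_lower_bound=prev_bound,
        )

    def _prevalence(self, alpha, n_second_level, rng):
        if self.results is None:
            raise ConfigurationError(
                "prevalence inference needs full per-subject results with "
                "stored permutation distributions"
            )
        if any(r.permuted_per_analysis is None for r in self.results):
            raise ConfigurationError(
                "prevalence inference requires permute_labels=True decoding"
            )
        # one first-level permutation value per repetition: the mean over folds
        perms = np.stack(
            [r.permuted_per_analysis.mean(axis=2).T for r in self.results]
        )  # (n_subj, m, n_steps)
        return prevalence_minimum_statistic(
            self.subject_matrix,
            perms,
            alpha=alpha,
            n_second_level=n_second_level,
            rng=rng,
        )
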