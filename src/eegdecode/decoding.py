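"""Per-subject sliding-window decoding engine.

The engine walks an analysis-window grid over the epoch and, in every
window, estimates how well a linear model discriminates the conditions of a
discrimination group (classification), predicts a continuous per-trial
variable (support vector regression), or generalises from one condition
context to another (cross-condition decoding).

Cross-validation scheme: exemplars of each condition are balanced to the
smallest condition count, randomly divided into ``k`` equal sets (left-over
exemplars are excluded for that cycle), and each set serves once as test
data while the model is trained on the other ``k - 1``. The full cycle is
repeated ``m`` times with fresh, independent set draws; the reported
performance per window is the mean over all ``m x k`` analyses. With
``permute_labels`` the identical procedure runs a second time on the same
data and fold memberships but with the condition labels independently
re-shuffled in every repetition, yielding an empirical chance distribution
that inherits any biases of the real data.

Performance metrics: percent correct for classification, the Fisher-Z
transformed Pearson correlation between predicted and true labels for
regression. The default backend is a linear soft-margin SVM (C = 1) or SVR
(C = 0.1); any estimator with ``fit``/``predict`` can be injected through
``DecodingConfig.backend_factory``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import DecodingConfig, EpochedDataset
from .errors import ConfigurationError, DataError, DegenerateDataError
from .weights import FeatureWeightMap, haufe_correct
from .windowing import PatternMatrix, extract_patterns, make_window_plan

#: Fisher-Z clamp: |r| is limited to 1 - _R_CLAMP before arctanh
_R_CLAMP = 1e-12


def _safe_activation(w: np.ndarray, X_train: np.ndarray) -> np.ndarray:
    """Haufe correction; an undefined pattern (zero projected variance)
    contributes a zero vector instead of aborting the analysis."""
    try:
        return haufe_correct(w, X_train)
    except DegenerateDataError:
        return np.zeros_like(w)


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for a (step, repetition, purpose) key."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF,
                               spawn_key=tuple(int(k) for k in key))
    )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def balance_trials(
    patterns: dict[int, np.ndarray], rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Equalise exemplar counts across conditions by seeded subsampling.

    ``patterns`` maps condition -> (n_exemplars, n_features); every condition
    is reduced to the smallest count by uniform sampling without replacement.
    """
    counts = {c: np.asarray(p).shape[0] for c, p in patterns.items()}
    if any(n == 0 for n in counts.values()):
        empty = [c for c, n in counts.items() if n == 0]
        raise DataError(f"condition(s) {empty} have no exemplars")
    n_min = min(counts.values())
    out = {}
    for cond in sorted(patterns):
        p = np.asarray(patterns[cond])
        if p.shape[0] == n_min:
            out[cond] = p
        else:
            keep = np.sort(rng.choice(p.shape[0], size=n_min, replace=False))
            out[cond] = p[keep]
    return out


def block_average(pattern: PatternMatrix) -> PatternMatrix:
    """Average exemplars within each run, one averaged exemplar per run."""
    if pattern.runs is None:
        raise DataError("pattern matrix lacks run provenance; cannot block-average")
    runs = np.unique(pattern.runs)
    vectors = np.vstack(
        [pattern.vectors[pattern.runs == r].mean(axis=0) for r in runs]
    )
    labels = None
    if pattern.labels is not None:
        labels = np.array(
            [np.mean(pattern.labels[pattern.runs == r]) for r in runs]
        )
    return PatternMatrix(
        vectors=vectors,
        labels=labels,
        feature_layout=pattern.feature_layout,
        runs=runs,
    )


def pool_blocks(pattern: PatternMatrix) -> PatternMatrix:
    """Pool exemplars across runs (identity on the concatenated layout).

    Extraction already concatenates trials in run order; pooling keeps every
    trial as its own exemplar and retains run provenance.
    """
    return pattern


@dataclass
class CvAssignment:
    """Random division of one condition's exemplars into k equal sets.

    ``sets`` is a (k, n_per_set) index array; ``excluded`` holds the
    ``n mod k`` left-over exemplar indices dropped for this cycle.
    """

    sets: np.ndarray
    excluded: np.ndarray

    @property
    def k(self) -> int:
        return self.sets.shape[0]

    @property
    def n_per_set(self) -> int:
        return self.sets.shape[1]


def assign_cv_sets(
    n_exemplars: int, k: int, rng: np.random.Generator
) -> CvAssignment:
    """Uniform-random assignment of exemplars to k equal cross-validation sets."""
    if n_exemplars < k:
        raise ConfigurationError(
            f"{n_exemplars} exemplars cannot fill k={k} cross-validation sets; "
            "choose a smaller k"
        )
    n_per_set = n_exemplars // k
    perm = rng.permutation(n_exemplars)
    return CvAssignment(
        sets=perm[: k * n_per_set].reshape(k, n_per_set),
        excluded=np.sort(perm[k * n_per_set :]),
    )


# ---------------------------------------------------------------------------
# Backend and single train/test analysis
# ---------------------------------------------------------------------------


def _make_backend(config: DecodingConfig):
    if config.backend_factory is not None:
        return config.backend_factory(config)
    from sklearn.svm import SVC, SVR

    if config.analysis_type == "regression":
        return SVR(kernel="linear", C=config.effective_cost)
    return SVC(kernel="linear", C=config.effective_cost)


def fisher_z(r: float) -> float:
    """Inverse hyperbolic tangent of r, clamped away from |r| = 1."""
    return float(np.arctanh(np.clip(r, -1.0 + _R_CLAMP, 1.0 - _R_CLAMP)))


def _score_regression(pred: np.ndarray, true: np.ndarray) -> tuple[float, bool]:
    """Fisher-Z correlation; (0, True) when the correlation is undefined."""
    if np.std(pred) == 0 or np.std(true) == 0:
        return 0.0, True
    r = float(np.corrcoef(pred, true)[0, 1])
    return fisher_z(r), False


def _fit_score(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    config: DecodingConfig,
) -> tuple[float, np.ndarray | None, bool]:
    """Fit the backend once; return (score, primal weights or None, degenerate)."""
    if config.zscore_features:
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd
    model = _make_backend(config)
    model.fit(X_train, y_train)
    pred = np.asarray(model.predict(X_test))
    if config.analysis_type == "regression":
        score, degenerate = _score_regression(pred, np.asarray(y_test, float))
    else:
        score = 100.0 * float(np.mean(pred == np.asarray(y_test)))
        degenerate = False
    weights = None
    coef = getattr(model, "coef_", None)
    if coef is not None:
        coef = np.asarray(coef)
        if coef.ndim == 1 or coef.shape[0] == 1:
            weights = coef.ravel().astype(np.float64)
    return score, weights, degenerate


def train_and_test(
    train: PatternMatrix, test: PatternMatrix, config: DecodingConfig
) -> tuple[float, np.ndarray | None]:
    """Train the configured linear model and score it on held-out patterns.

    Classification returns percent correct over the test exemplars;
    regression returns the Fisher-Z transformed correlation between predicted
    and true labels. The second element is the fitted primal weight vector
    for binary/regression linear models, ``None`` otherwise.
    """
    if train.n_features != test.n_features:
        raise ConfigurationError(
            f"train ({train.n_features}) and test ({test.n_features}) "
            "feature counts differ"
        )
    if train.labels is None or test.labels is None:
        raise DataError("train and test pattern matrices need labels")
    score, weights, _ = _fit_score(
        train.vectors, train.labels, test.vectors, test.labels, config
    )
    return score, weights


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------


@dataclass
class DecodingResult:
    """Per-subject decoding performance across analysis windows.

    ``accuracy`` is the mean over the ``m x k`` analyses of each window
    (percent correct, or Fisher-Z for regression); ``per_analysis`` keeps
    every single analysis (shape ``(n_steps, m, k)``). Permuted-label
    analogues are present when the analysis was run with
    ``permute_labels=True``. ``feature_weights`` holds raw and
    Haufe-corrected per-feature weights plus the per-channel map, when the
    backend exposes a primal weight vector.
    """

    accuracy: np.ndarray
    per_analysis: np.ndarray
    permuted_accuracy: np.ndarray | None
    permuted_per_analysis: np.ndarray | None
    feature_weights: FeatureWeightMap | None
    window_times_ms: np.ndarray
    n_classes: int
    config: DecodingConfig
    group: tuple[int, ...]
    degenerate_scores: int = 0

    @property
    def n_steps(self) -> int:
        return self.accuracy.shape[0]

    @property
    def chance_level(self) -> float | None:
        """Theoretical chance accuracy in percent (None for regression)."""
        if self.config.analysis_type == "regression":
            return None
        return 100.0 / self.n_classes

    def summary(self):
        """Per-window summary table (pandas DataFrame)."""
        import pandas as pd

        d = {
            "window_start_ms": self.window_times_ms[:, 0],
            "window_end_ms": self.window_times_ms[:, 1],
            "accuracy": self.accuracy,
        }
        if self.permuted_accuracy is not None:
            d["permuted_accuracy"] = self.permuted_accuracy
        return pd.DataFrame(d)

    def save(self, path: str | Path) -> None:
        """Write the result to a single structured ``.npz`` file."""
        payload: dict[str, np.ndarray] = {
            "accuracy": self.accuracy,
            "per_analysis": self.per_analysis,
            "window_times_ms": self.window_times_ms,
            "n_classes": np.array(self.n_classes),
            "group": np.array(self.group),
            "degenerate_scores": np.array(self.degenerate_scores),
            "config_json": np.array(json.dumps(self.config.to_dict())),
        }
        if self.permuted_per_analysis is not None:
            payload["permuted_accuracy"] = self.permuted_accuracy
            payload["permuted_per_analysis"] = self.permuted_per_analysis
        if self.feature_weights is not None:
            fw = self.feature_weights
            payload["fw_raw"] = fw.raw
            payload["fw_corrected"] = fw.corrected
            if fw.per_channel is not None:
                payload["fw_per_channel"] = fw.per_channel
            payload["fw_layout"] = np.array(
                [(ch, -1 if t is None else t) for ch, t in fw.feature_layout]
            )
            payload["fw_mode"] = np.array(fw.mode)
        np.savez(Path(path), **payload)

    @classmethod
    def load(cls, path: str | Path) -> "DecodingResult":
        with np.load(Path(path), allow_pickle=False) as f:
            config = DecodingConfig.from_dict(json.loads(str(f["config_json"])))
            fw = None
            if "fw_raw" in f:
                layout = tuple(
                    (int(ch), None if t == -1 else int(t))
                    for ch, t in f["fw_layout"]
                )
                fw = FeatureWeightMap(
                    raw=f["fw_raw"],
                    corrected=f["fw_corrected"],
                    per_channel=f["fw_per_channel"] if "fw_per_channel" in f else None,
                    feature_layout=layout,
                    mode=str(f["fw_mode"]),
                )
            return cls(
                accuracy=f["accuracy"],
                per_analysis=f["per_analysis"],
                permuted_accuracy=(
                    f["permuted_accuracy"] if "permuted_accuracy" in f else None
                ),
                permuted_per_analysis=(
                    f["permuted_per_analysis"]
                    if "permuted_per_analysis" in f
                    else None
                ),
                feature_weights=fw,
                window_times_ms=f["window_times_ms"],
                n_classes=int(f["n_classes"]),
                config=config,
                group=tuple(int(g) for g in f["group"]),
                degenerate_scores=int(f["degenerate_scores"]),
            )


# ---------------------------------------------------------------------------
# Subject-level model object
# ---------------------------------------------------------------------------


class SubjectDecoder:
    """Sliding-window decoding model for one subject.

    Parameters
    ----------
    dataset
        Validated :class:`~eegdecode.data.EpochedDataset`.
    config
        :class:`~eegdecode.data.DecodingConfig`; the first discrimination
        group is analysed unless ``group`` overrides it.
    group
        Condition indices to contrast (classification), the single condition
        to regress (regression). Ignored for cross-condition analyses, which
        use both configured groups.

    ``fit()`` returns a :class:`DecodingResult`.
    """

    def __init__(
        self,
        dataset: EpochedDataset,
        config: DecodingConfig,
        group: Sequence[int] | None = None,
    ):
        self.dataset = dataset
        self.config = config
        if config.analysis_type == "cross_condition":
            self.group = tuple(config.discrimination_groups[0])
            self.test_group = tuple(config.discrimination_groups[1])
        else:
            self.group = tuple(group or config.discrimination_groups[0])
            self.test_group = None
            if config.analysis_type == "regression" and len(self.group) != 1:
                raise ConfigurationError(
                    "regression uses exactly one condition per analysis"
                )

    # -- helpers -----------------------------------------------------------

    def _plan(self):
        rate = self.dataset.sampling_rate_hz
        width = self.config.window_width_samples(rate)
        step = self.config.step_samples(rate)
        return make_window_plan(self.dataset.n_timepoints, width, step), width

    def _prepared_patterns(
        self, dataset: EpochedDataset, start: int, width: int
    ) -> dict[int, PatternMatrix]:
        """Extract one window and apply block averaging or pooling."""
        pats = extract_patterns(
            dataset, start, width, self.config.mode, self.config.channel
        )
        if self.config.average_by_block:
            return {c: block_average(p) for c, p in pats.items()}
        return {c: pool_blocks(p) for c, p in pats.items()}

    def _track_weights(self) -> bool:
        if self.config.analysis_type == "regression":
            return True
        return len(self.group) == 2

    # -- fitting -----------------------------------------------------------

    def fit(self) -> DecodingResult:
        if self.config.analysis_type == "cross_condition":
            return self._fit_cross_condition()
        plan, width = self._plan()
        cfg = self.config
        reduced = self.dataset.reduce_conditions(self.group)
        k, m = cfg.k_folds, cfg.m_repetitions
        n_steps = plan.n_steps
        per_analysis = np.empty((n_steps, m, k))
        perm_analysis = np.empty((n_steps, m, k)) if cfg.permute_labels else None
        track = self._track_weights()
        raw_sum = corr_sum = None
        n_weight = 0
        degenerate = 0
        layout = None
        for si, start in enumerate(plan.starts):
            pats = self._prepared_patterns(reduced, start, width)
            layout = pats[1].feature_layout
            if cfg.analysis_type == "regression":
                if pats[1].labels is None:
                    raise DataError("regression requires per-trial svr_labels")
            for rep in range(m):
                rng = child_rng(cfg.rng_seed, si, rep, 0)
                folds_X, folds_y = self._draw_folds(pats, rng)
                for fold in range(k):
                    X_tr = np.vstack([folds_X[j] for j in range(k) if j != fold])
                    y_tr = np.concatenate(
                        [folds_y[j] for j in range(k) if j != fold]
                    )
                    score, w, deg = _fit_score(
                        X_tr, y_tr, folds_X[fold], folds_y[fold], cfg
                    )
                    per_analysis[si, rep, fold] = score
                    degenerate += deg
                    if track and w is not None:
                        a = _safe_activation(w, X_tr)
                        if raw_sum is None:
                            raw_sum = np.zeros((n_steps, w.size))
                            corr_sum = np.zeros((n_steps, w.size))
                        raw_sum[si] += w
                        corr_sum[si] += a
                        if si == 0:
                            n_weight += 1
                if cfg.permute_labels:
                    # labels are re-shuffled within each fold: the data-label
                    # pairing is destroyed while every fold keeps its exact
                    # class balance, so the empirical chance distribution is
                    # centred on the theoretical level instead of below it
                    # (globally shuffled labels create complementary class
                    # imbalances in train and test folds)
                    rng_p = child_rng(cfg.rng_seed, si, rep, 1)
                    split = [rng_p.permutation(y) for y in folds_y]
                    for fold in range(k):
                        X_tr = np.vstack(
                            [folds_X[j] for j in range(k) if j != fold]
                        )
                        y_tr = np.concatenate(
                            [split[j] for j in range(k) if j != fold]
                        )
                        score, _, deg = _fit_score(
                            X_tr, y_tr, folds_X[fold], split[fold], cfg
                        )
                        perm_analysis[si, rep, fold] = score
                        degenerate += deg
        fw = None
        if raw_sum is not None and n_weight > 0:
            fw = FeatureWeightMap.from_mean_weights(
                raw_sum / (m * k), corr_sum / (m * k), layout, cfg.mode
            )
        return DecodingResult(
            accuracy=per_analysis.reshape(n_steps, -1).mean(axis=1),
            per_analysis=per_analysis,
            permuted_accuracy=(
                perm_analysis.reshape(n_steps, -1).mean(axis=1)
                if perm_analysis is not None
                else None
            ),
            permuted_per_analysis=perm_analysis,
            feature_weights=fw,
            window_times_ms=plan.window_times_ms(
                self.dataset.sampling_rate_hz, self.dataset.epoch_start_ms
            ),
            n_classes=len(self.group) if cfg.analysis_type != "regression" else 1,
            config=cfg,
            group=self.group,
            degenerate_scores=degenerate,
        )

    def _draw_folds(
        self, pats: dict[int, PatternMatrix], rng: np.random.Generator
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Balance, assign CV sets, and materialise fold arrays for one draw."""
        cfg = self.config
        k = cfg.k_folds
        conds = sorted(pats)
        if cfg.analysis_type == "regression":
            p = pats[conds[0]]
            assign = assign_cv_sets(p.n_exemplars, k, rng)
            folds_X = [p.vectors[assign.sets[f]] for f in range(k)]
            folds_y = [p.labels[assign.sets[f]] for f in range(k)]
            return folds_X, folds_y
        balanced = balance_trials({c: pats[c].vectors for c in conds}, rng)
        n_min = balanced[conds[0]].shape[0]
        if n_min < k:
            raise ConfigurationError(
                f"smallest condition has {n_min} exemplars for k={k}; "
                "choose a smaller k"
            )
        assigns = {c: assign_cv_sets(n_min, k, rng) for c in conds}
        folds_X, folds_y = [], []
        for f in range(k):
            folds_X.append(
                np.vstack([balanced[c][assigns[c].sets[f]] for c in conds])
            )
            folds_y.append(
                np.concatenate(
                    [
                        np.full(assigns[c].n_per_set, ci, dtype=int)
                        for ci, c in enumerate(conds)
                    ]
                )
            )
        return folds_X, folds_y

    def _fit_cross_condition(self) -> DecodingResult:
        """Train on one condition context, test on a disjoint context.

        Train and test contexts are already independent, so no k-fold split
        is used; each of the ``m`` repetitions re-draws the balancing
        subsample of both contexts.
        """
        plan, width = self._plan()
        cfg = self.config
        train_group, test_group = self.group, self.test_group
        all_conds = tuple(train_group) + tuple(test_group)
        reduced = self.dataset.reduce_conditions(all_conds)
        # after re-indexing: train context -> 1..n, test context -> n+1..2n
        n_cls = len(train_group)
        m = cfg.m_repetitions
        n_steps = plan.n_steps
        per_analysis = np.empty((n_steps, m, 1))
        perm_analysis = np.empty((n_steps, m, 1)) if cfg.permute_labels else None
        track = n_cls == 2
        raw_sum = corr_sum = None
        layout = None
        degenerate = 0
        for si, start in enumerate(plan.starts):
            pats = self._prepared_patterns(reduced, start, width)
            layout = pats[1].feature_layout
            train_pats = {c: pats[c] for c in range(1, n_cls + 1)}
            test_pats = {c - n_cls: pats[c] for c in range(n_cls + 1, 2 * n_cls + 1)}
            for rep in range(m):
                rng = child_rng(cfg.rng_seed, si, rep, 0)
                X_tr, y_tr = _stack_balanced(train_pats, rng)
                X_te, y_te = _stack_balanced(test_pats, rng)
                score, w, deg = _fit_score(X_tr, y_tr, X_te, y_te, cfg)
                per_analysis[si, rep, 0] = score
                degenerate += deg
                if track and w is not None:
                    a = _safe_activation(w, X_tr)
                    if raw_sum is None:
                        raw_sum = np.zeros((n_steps, w.size))
                        corr_sum = np.zeros((n_steps, w.size))
                    raw_sum[si] += w
                    corr_sum[si] += a
                if cfg.permute_labels:
                    rng_p = child_rng(cfg.rng_seed, si, rep, 1)
                    score, _, deg = _fit_score(
                        X_tr, rng_p.permutation(y_tr), X_te, y_te, cfg
                    )
                    perm_analysis[si, rep, 0] = score
                    degenerate += deg
        fw = None
        if raw_sum is not None:
            fw = FeatureWeightMap.from_mean_weights(
                raw_sum / m, corr_sum / m, layout, cfg.mode
            )
        return DecodingResult(
            accuracy=per_analysis.reshape(n_steps, -1).mean(axis=1),
            per_analysis=per_analysis,
            permuted_accuracy=(
                perm_analysis.reshape(n_steps, -1).mean(axis=1)
                if perm_analysis is not None
                else None
            ),
            permuted_per_analysis=perm_analysis,
            feature_weights=fw,
            window_times_ms=plan.window_times_ms(
                self.dataset.sampling_rate_hz, self.dataset.epoch_start_ms
            ),
            n_classes=n_cls,
            config=cfg,
            group=train_group,
            degenerate_scores=degenerate,
        )


def _stack_balanced(
    pats: dict[int, PatternMatrix], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    conds = sorted(pats)
    balanced = balance_trials({c: pats[c].vectors for c in conds}, rng)
    X = np.vstack([balanced[c] for c in conds])
    y = np.concatenate(
        [
            np.full(balanced[c].shape[0], ci, dtype=int)
            for ci, c in enumerate(conds)
        ]
    )
    return X, y


def run_subject_decoding(
    dataset: EpochedDataset,
    config: DecodingConfig,
    group: Sequence[int] | None = None,
) -> DecodingResult:
    """Functional wrapper: build a :class:`SubjectDecoder` and fit it."""
    return SubjectDecoder(dataset, config, group=group).fit()


def cross_condition_decode(
    dataset: EpochedDataset,
    train_group: Sequence[int],
    test_group: Sequence[int],
    config: DecodingConfig,
) -> DecodingResult:
    """Train on ``train_group`` conditions, evaluate on ``test_group``."""
    cfg = config.replace(
        analysis_type="cross_condition",
        discrimination_groups=[tuple(train_group), tuple(test_group)],
    )
    return SubjectDecoder(dataset, cfg).fit()
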