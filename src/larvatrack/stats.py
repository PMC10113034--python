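"""Group level machinery: track filter, random-forest phenotyping, test battery."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .record import TrackRecord

N_TREES = 500


def filter_tracks(
    tracks: Sequence[TrackRecord], video_len_frames: int
) -> list[TrackRecord]:
    """Keep tracks covering at least half the video (boundary inclusive).

    At most one surviving track can belong to any physical animal, since two
    disjoint fragments of one animal cannot both span half the video.
    """
    return [t for t in tracks if t.duration_frames >= video_len_frames / 2]


@dataclass
class CohortTable:
    features: pd.DataFrame  # rows = larvae, columns = behavioural attributes
    labels: np.ndarray  # class label per row

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree in length")

    def dropna(self) -> "CohortTable":
        ok = self.features.notna().all(axis=1).to_numpy()
        return CohortTable(self.features.loc[ok].reset_index(drop=True), self.labels[ok])


@dataclass
class RFResult:
    accuracy: float  # unweighted mean of per-class correct rates
    confusion: pd.DataFrame  # rows true, columns predicted, pooled out-of-fold
    classes: list
    importance_mean_rank: pd.Series | None = None


def accuracy_from_confusion(confusion: np.ndarray) -> float:
    """Average of the per-class correct-assignment rates."""
    confusion = np.asarray(confusion, dtype=float)
    rates = np.diag(confusion) / confusion.sum(axis=1)
    return float(np.mean(rates))


def _fit_cv(
    table: CohortTable, seed: int, n_splits: int = 5, n_repeats: int = 3
) -> tuple[np.ndarray, list, np.ndarray]:
    """5-fold CV repeated with reshuffling; pooled confusion + importances."""
    X = table.features.to_numpy(dtype=float)
    y = table.labels
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = pd.Series(y).value_counts()
    if counts.min() < 10:
        raise ValueError("need at least 10 rows per class")
    idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    importances = []
    rng = np.random.default_rng(seed)
    for rep in range(n_repeats):
        skf = StratifiedKFold(
            n_splits=n_splits, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for train, test in skf.split(X, y):
            clf = RandomForestClassifier(
                n_estimators=N_TREES, random_state=int(rng.integers(2**31)), n_jobs=1
            )
            clf.fit(X[train], y[train])
            pred = clf.predict(X[test])
            for yt, yp in zip(y[test], pred):
                confusion[idx[yt], idx[yp]] += 1
            importances.append(clf.feature_importances_)
    return confusion, classes, np.mean(importances, axis=0)


def rf_classify(table: CohortTable, seed: int = 0) -> RFResult:
    """Random forest under 5-fold CV repeated 3 times (shuffled between reps)."""
    confusion, classes, _ = _fit_cv(table, seed)
    cm = pd.DataFrame(confusion, index=classes, columns=classes)
    return RFResult(accuracy_from_confusion(confusion), cm, classes)


def rf_importance(
    table: CohortTable, n_runs: int = 10, seed: int = 0
) -> pd.Series:
    """Attributes sorted by mean importance rank over repeated CV models.

    Rank 1 is the most important attribute within a run; the returned series
    maps attribute name to its mean rank, ascending (best first).
    """
    names = list(table.features.columns)
    ranks = np.zeros((n_runs, len(names)))
    for run in range(n_runs):
        _, _, imp = _fit_cv(table, seed + 7919 * run)
        order = np.argsort(imp)[::-1]
        r = np.empty(len(names))
        r[order] = np.arange(1, len(names) + 1)
        ranks[run] = r
    mean_rank = pd.Series(ranks.mean(axis=0), index=names).sort_values()
    return mean_rank


@dataclass
class StatTestResult:
    test: str  # 'KW' | 'MW' | 'WS' | 'SC'
    statistic: float
    p_raw: float
    p_adjusted: float = np.nan
    significant: bool = False
    label: str = ""
    undefined: bool = False


def holm_adjust(results: list[StatTestResult], alpha: float = 0.05) -> None:
    """In-place Bonferroni-Holm step-down over one declared family."""
    defined = [r for r in results if not r.undefined and np.isfinite(r.p_raw)]
    if not defined:
        return
    reject, p_adj, _, _ = multipletests(
        [r.p_raw for r in defined], alpha=alpha, method="holm"
    )
    for r, pa, rej in zip(defined, p_adj, reject):
        r.p_adjusted = float(pa)
        r.significant = bool(rej)


def run_tests(
    data,
    kind: str,
    labels: list[str] | None = None,
    alpha: float = 0.05,
    holm: bool = True,
) -> list[StatTestResult]:
    """Two-tailed non-parametric battery with Holm correction per family.

    kind='KW': ``data`` is a list of groups; a Kruskal-Wallis test is run
    and, if significant, pairwise Mann-Whitney tests follow (all p-values in
    one family). kind='MW'/'WS'/'SC': ``data`` is a list of pairs of series.
    """
    results: list[StatTestResult] = []

    def _safe(testfun, *args, name="", test=""):
        try:
            stat, p = testfun(*args)
            return StatTestResult(test, float(stat), float(p), label=name)
        except ValueError:
            return StatTestResult(test, np.nan, np.nan, label=name, undefined=True)

    if kind == "KW":
        groups = [np.asarray(g, dtype=float) for g in data]
        names = labels or [f"g{i}" for i in range(len(groups))]
        kw = _safe(sps.kruskal, *groups, name="KW:" + "|".join(names), test="KW")
        results.append(kw)
        if np.isfinite(kw.p_raw) and kw.p_raw < alpha:
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    results.append(
                        _safe(
                            lambda a, b: sps.mannwhitneyu(a, b, alternative="two-sided"),
                            groups[i],
                            groups[j],
                            name=f"{names[i]} vs {names[j]}",
                            test="MW",
                        )
                    )
    elif kind in ("MW", "WS", "SC"):
        fun = {
            "MW": lambda a, b: sps.mannwhitneyu(a, b, alternative="two-sided"),
            "WS": lambda a, b: sps.wilcoxon(a, b),
            "SC": lambda a, b: sps.spearmanr(a, b),
        }[kind]
        names = labels or [f"pair{i}" for i in range(len(data))]
        for (a, b), name in zip(data, names):
            results.append(
                _safe(fun, np.asarray(a, float), np.asarray(b, float), name=name, test=kind)
            )
    else:
        raise ValueError(f"unknown test kind {kind!r}")

    if holm:
        holm_adjust(results, alpha)
    return results


def type_I_error_suite(
    simulator: Callable[[np.random.Generator], tuple],
    kind: str,
    n_reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of a raw test on null data from ``simulator``."""
    rng = np.random.default_rng(seed)
    fun = {
        "MW": lambda a, b: sps.mannwhitneyu(a, b, alternative="two-sided"),
        "WS": lambda a, b: sps.wilcoxon(a, b),
        "SC": lambda a, b: sps.spearmanr(a, b),
        "KW": sps.kruskal,
    }[kind]
    rejections = 0
    for _ in range(n_reps):
        args = simulator(rng)
        _, p = fun(*args)
        if p < alpha:
            rejections += 1
    return rejections / n_reps
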