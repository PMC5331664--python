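"""Evaluation of a distance measure against a known grouping.

Two complementary assessments are provided.  The ROC analysis asks whether
ranking pairs by distance separates same-group ("positive") pairs from
different-group ("negative") pairs; the area under the curve (AUC) is 1
for a perfect ranking and 0.5 for an uninformative one.  The
classification experiment goes one step further: sequences are split at
random into training and test halves within each group, and each test
sequence is assigned to the group whose training members lie at the
smallest mean distance; the fraction of correct assignments (trace of the
confusion matrix over its total) is the classifier's efficiency.  A
seeded uniform RANDOM distance serves as the null baseline: its expected
efficiency with G balanced groups is 1/G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kernel import PairMatrix


class EvaluationError(ValueError):
    """Raised for invalid evaluation input."""


@dataclass(frozen=True)
class RocResult:
    """ROC curve and AUC for one threshold sweep.

    ``fpr``/``tpr`` include the (0, 0) and (1, 1) endpoints; ``auc`` is the
    Mann-Whitney rank statistic with midrank tie handling, which equals the
    trapezoidal area under the tie-grouped curve.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    mode: str
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count table C(i, j): test items of group i assigned to group j."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        n = len(self.labels)
        if counts.shape != (n, n) or np.any(counts < 0):
            raise EvaluationError("confusion matrix must be square and non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def efficiency(self) -> float:
        """Fraction correctly classified: trace over total."""
        total = int(self.counts.sum())
        if total == 0:
            raise EvaluationError("empty confusion matrix")
        return float(np.trace(self.counts)) / total


def _pair_arrays(
    distances: PairMatrix, groups: dict[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle distances and the group labels of both pair members."""
    unlabeled = [sid for sid in distances.ids if sid not in groups]
    if unlabeled:
        raise EvaluationError(f"unlabeled ids: {', '.join(sorted(unlabeled))}")
    labels = np.array([groups[sid] for sid in distances.ids])
    iu, ju = np.triu_indices(len(distances.ids), k=1)
    return distances.values[iu, ju], np.stack([labels[iu], labels[ju]])


def _rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUC = P(positive scored better than negative), midranks for ties.

    ``scores`` are distances: smaller means predicted-positive earlier.
    """
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC needs at least one positive and one negative pair")
    ranks = stats.rankdata(scores, method="average")
    pos_rank_sum = ranks[positive].sum()
    # positives ranked low (small distance) => large AUC
    return float(
        (n_pos * n_neg + n_pos * (n_pos + 1) / 2.0 - pos_rank_sum) / (n_pos * n_neg)
    )


def roc_analysis(
    distances: PairMatrix, groups: dict[str, str], mode: str = "pooled"
) -> RocResult:
    """ROC analysis of a distance matrix against group labels.

    A threshold sweeps the distances; pairs below it are called positive.
    ``mode="pooled"`` treats any same-group pair as positive regardless of
    which group it is; ``mode="per-group:<label>"`` restricts positives to
    pairs inside the named group, every other pair (including same-group
    pairs of other groups) counting as negative.
    """
    if len(set(groups.values())) < 2:
        raise EvaluationError("need at least two groups")
    d, pair_labels = _pair_arrays(distances, groups)
    same = pair_labels[0] == pair_labels[1]
    if mode == "pooled":
        positive = same
    elif mode.startswith("per-group:"):
        label = mode.split(":", 1)[1]
        members = sum(1 for g in groups.values() if g == label)
        if members < 2:
            raise EvaluationError(
                f"group {label!r} has {members} member(s); need >= 2 for a ROC"
            )
        positive = same & (pair_labels[0] == label)
    else:
        raise EvaluationError(f"unknown ROC mode {mode!r}")

    auc = _rank_auc(d, positive)
    order = np.argsort(d, kind="stable")
    d_sorted, pos_sorted = d[order], positive[order]
    # group tied thresholds so the curve is a step/segment per distinct value
    distinct = np.nonzero(np.diff(d_sorted, append=np.inf))[0]
    tp = np.cumsum(pos_sorted)[distinct]
    fp = np.cumsum(~pos_sorted)[distinct]
    n_pos, n_neg = int(positive.sum()), int((~positive).sum())
    return RocResult(
        thresholds=np.concatenate([[-np.inf], d_sorted[distinct]]),
        fpr=np.concatenate([[0.0], fp / n_neg]),
        tpr=np.concatenate([[0.0], tp / n_pos]),
        auc=auc,
        mode=mode,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def pearson(xs, ys) -> float:
    """Pearson correlation coefficient between two score lists."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size != ys.size:
        raise EvaluationError("score lists must have equal length")
    if xs.size < 3:
        raise EvaluationError("need at least three score pairs")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise EvaluationError("zero variance in one of the score lists")
    return float(stats.pearsonr(xs, ys).statistic)


def classify_experiment(
    distances: PairMatrix,
    groups: dict[str, str],
    n_repeats: int = 1000,
    seed: int = 0,
) -> tuple[list[ConfusionMatrix], float]:
    """Repeated nearest-group classification from a distance matrix.

    Each repeat splits every group at random into halves (the extra member
    of an odd group goes to training), then assigns each test sequence to
    the group with the smallest mean distance to its training members.
    Ties go to the lexicographically smallest group label.  Returns the
    per-repeat confusion matrices and the mean efficiency.
    """
    if n_repeats < 1:
        raise EvaluationError("n_repeats must be >= 1")
    unlabeled = [sid for sid in distances.ids if sid not in groups]
    if unlabeled:
        raise EvaluationError(f"unlabeled ids: {', '.join(sorted(unlabeled))}")
    labels = sorted(set(groups[sid] for sid in distances.ids))
    label_pos = {g: i for i, g in enumerate(labels)}
    members: dict[str, np.ndarray] = {
        g: np.array([i for i, sid in enumerate(distances.ids) if groups[sid] == g])
        for g in labels
    }
    for g, idx in members.items():
        if idx.size < 2:
            raise EvaluationError(f"group {g!r} has fewer than two members")

    rng = np.random.default_rng(seed)
    d = distances.values
    results: list[ConfusionMatrix] = []
    for _ in range(n_repeats):
        train: dict[str, np.ndarray] = {}
        test_idx: list[int] = []
        test_grp: list[str] = []
        for g in labels:
            perm = rng.permutation(members[g])
            n_train = (perm.size + 1) // 2  # odd group: extra member trains
            train[g] = perm[:n_train]
            test_idx.extend(perm[n_train:])
            test_grp.extend([g] * (perm.size - n_train))
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        if test_idx:
            # mean distance from each test item to each group's training set;
            # argmin over the sorted labels makes ties lexicographic
            mean_d = np.column_stack(
                [d[np.ix_(test_idx, train[g])].mean(axis=1) for g in labels]
            )
            assigned = np.argmin(mean_d, axis=1)
            for true_g, j in zip(test_grp, assigned):
                counts[label_pos[true_g], j] += 1
        results.append(ConfusionMatrix(tuple(labels), counts))
    mean_eff = float(np.mean([c.efficiency for c in results]))
    return results, mean_eff


def random_distance(ids, seed: int = 0) -> PairMatrix:
    """Uniform(0, 1) symmetric null distance matrix (the RANDOM baseline)."""
    ids = tuple(ids)
    if len(ids) < 2:
        raise EvaluationError("need at least two ids")
    rng = np.random.default_rng(seed)
    n = len(ids)
    upper = rng.uniform(0.0, 1.0, size=n * (n - 1) // 2)
    values = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    values[iu, ju] = upper
    values[ju, iu] = upper
    return PairMatrix(ids, values, "distance")
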