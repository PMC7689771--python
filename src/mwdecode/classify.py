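"""Trial labeling, RBF-SVM training and cross-validated evaluation.

Three binary labelings of the visual search trials are supported:

* ``demand`` — counting blocks are high demand, non-counting blocks low;
* ``vigilance`` — per-participant chronological median split (first half
  high vigilance, second half low);
* ``selfreport`` — the three trials preceding each thought probe inherit
  its rating; negative ratings mean mind-wandering, positive on-task,
  zero ("uncertain") is excluded.  SART trials carry only this labeling.

The positive class (label 1) is always the "off" state: mind-wandering,
low demand, low vigilance.

Training follows a fixed protocol: per-feature z-transform estimated on
the training sample only, random over-sampling of the minority class to
parity, and an RBF SVM with C = 1 and gamma = 1/(feature dimension).
Evaluation combines an outer leave-one-participant-out loop with a
diagnostic inner 10-fold CV, plus across-task prediction of the SART
trials by each outer-fold model.  Accuracies are compared to the
data-size-corrected chance level of a binary classifier (the binomial
inverse-CDF threshold of Combrisson & Jerbi).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledSet",
    "Scaler",
    "TrainedModel",
    "EvalReport",
    "DecodingRun",
    "SCHEMES",
    "attach_probe_ratings",
    "assign_labels",
    "prepare_training",
    "train_svm",
    "run_lopocv",
    "cross_task_predict",
    "corrected_chance_level",
    "evaluate_vs_chance",
]

SCHEMES = ("demand", "vigilance", "selfreport")
N_TRIALS_BEFORE_PROBE = 3


# ---------------------------------------------------------------------------
# labeling


def attach_probe_ratings(
    trials: pd.DataFrame,
    probes: pd.DataFrame,
    n_before: int = N_TRIALS_BEFORE_PROBE,
) -> pd.DataFrame:
    """Attach each probe's rating to the ``n_before`` trials preceding it.

    ``trials`` needs participant/task/onset_sample columns; ``probes``
    needs participant/task/onset_sample/rating.  Returns a copy of
    ``trials`` with a ``rating`` column (NaN on unprobed trials).
    """
    out = trials.copy()
    out["rating"] = np.nan
    for (part, task), probe_grp in probes.groupby(["participant", "task"]):
        sel = (out["participant"] == part) & (out["task"] == task)
        idx = out.index[sel]
        onsets = out.loc[idx, "onset_sample"].to_numpy()
        order = np.argsort(onsets)
        for _, probe in probe_grp.iterrows():
            before = order[onsets[order] < probe["onset_sample"]]
            chosen = idx[before[-n_before:]]
            out.loc[chosen, "rating"] = probe["rating"]
    return out


@dataclass
class LabeledSet:
    """Row indices into a feature matrix with binary labels.

    ``y`` uses 1 for the "off" state (mind-wandering / low demand / low
    vigilance) and 0 for the "on" state.
    """

    indices: np.ndarray
    y: np.ndarray
    participants: np.ndarray
    scheme: str

    def __len__(self) -> int:
        return self.indices.size

    def subset(self, mask: np.ndarray) -> "LabeledSet":
        return LabeledSet(
            self.indices[mask], self.y[mask], self.participants[mask],
            self.scheme,
        )


def assign_labels(
    trial_table: pd.DataFrame, scheme: str, task: str = "VS"
) -> LabeledSet:
    """Build a labeled trial set under one labeling scheme.

    ``trial_table`` rows must align with the feature-matrix rows.  SART
    trials only accept the selfreport scheme.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if task == "SART" and scheme != "selfreport":
        raise ValueError("SART trials are labeled by self-report only")
    t = trial_table.reset_index(drop=True)
    in_task = t["task"] == task

    if scheme == "demand":
        idx = np.flatnonzero(in_task)
        y = (t.loc[idx, "condition"] == "noncounting").to_numpy(dtype=int)
    elif scheme == "vigilance":
        idx_list, y_list = [], []
        for _, grp in t[in_task].groupby("participant"):
            order = grp["onset_sample"].rank(method="first").to_numpy()
            half = order > len(grp) / 2.0  # second half = low vigilance
            idx_list.append(grp.index.to_numpy())
            y_list.append(half.astype(int))
        idx = np.concatenate(idx_list) if idx_list else np.array([], dtype=int)
        y = np.concatenate(y_list) if y_list else np.array([], dtype=int)
    else:  # selfreport
        rated = in_task & t["rating"].notna() & (t["rating"] != 0)
        idx = np.flatnonzero(rated)
        y = (t.loc[idx, "rating"] < 0).to_numpy(dtype=int)

    if idx.size == 0:
        raise ValueError(f"no labelable {task} trials under scheme {scheme!r}")
    parts = t.loc[idx, "participant"].to_numpy()
    return LabeledSet(indices=idx, y=np.asarray(y), participants=parts,
                      scheme=scheme)


# ---------------------------------------------------------------------------
# training protocol


@dataclass
class Scaler:
    """Frozen per-feature z-transform estimated on training data."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # bool mask of features with nonzero training variance

    @property
    def n_dropped(self) -> int:
        return int((~self.kept).sum())

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean) / np.where(self.kept, self.sd, 1.0)
        return Z[:, self.kept]


@dataclass
class Prepared:
    X: np.ndarray  # scaled, balanced training features
    y: np.ndarray
    scaler: Scaler
    indices: np.ndarray  # balanced row indices into the unscaled input
    oversample_counts: dict


def prepare_training(X: np.ndarray, y: np.ndarray, seed: int) -> Prepared:
    """Z-transform and balance a training sample by random over-sampling.

    The scaler is estimated on the unbalanced training sample; the
    minority class is then resampled with replacement up to the majority
    count.  Majority indices are preserved exactly.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training sample must contain both classes")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    kept = sd > 0
    if not kept.any():
        raise ValueError("degenerate input: all features have zero variance")
    if not kept.all():
        logger.info("dropping %d zero-variance feature(s)", (~kept).sum())
    scaler = Scaler(mean=mean, sd=sd, kept=kept)

    rng = np.random.default_rng(seed)
    idx = np.arange(y.size)
    n_max = counts.max()
    extra = []
    for cls, cnt in zip(classes, counts):
        if cnt < n_max:
            extra.append(rng.choice(idx[y == cls], size=n_max - cnt,
                                    replace=True))
    balanced = np.concatenate([idx] + extra) if extra else idx
    return Prepared(
        X=scaler.transform(X[balanced]),
        y=y[balanced],
        scaler=scaler,
        indices=balanced,
        oversample_counts={int(c): int(n_max - n) for c, n in
                           zip(classes, counts)},
    )


@dataclass
class TrainedModel:
    """Fitted RBF-SVM with its frozen scaler and training manifest."""

    scheme: str
    scaler: Scaler
    svc: object
    gamma: float
    manifest: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(self.scaler.transform(X))


def train_svm(
    prepared: Prepared, scheme: str = "", C: float = 1.0
) -> TrainedModel:
    """RBF SVM with C = 1 and gamma = 1/(feature dimension)."""
    from sklearn.svm import SVC

    if prepared.X.shape[0] < 4 or np.unique(prepared.y).size < 2:
        raise ValueError("need at least two samples per class")
    gamma = 1.0 / prepared.X.shape[1]
    svc = SVC(C=C, kernel="rbf", gamma=gamma)
    svc.fit(prepared.X, prepared.y)
    return TrainedModel(
        scheme=scheme,
        scaler=prepared.scaler,
        svc=svc,
        gamma=gamma,
        manifest={
            "n_train": int(prepared.X.shape[0]),
            "oversampled": prepared.oversample_counts,
            "dropped_features": prepared.scaler.n_dropped,
        },
    )


# ---------------------------------------------------------------------------
# chance statistics


def corrected_chance_level(n_test: int, alpha: float = 0.05) -> float:
    """Data-size-corrected chance level of a balanced binary classifier.

    The binomial inverse-CDF threshold: the largest accuracy k/n still
    compatible with guessing at level ``alpha`` (accuracies strictly above
    it are significant).  Decreases toward 0.5 as n grows.
    """
    if n_test < 1:
        raise ValueError("n_test must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    k = stats.binom.ppf(1.0 - alpha, n_test, 0.5)
    return float(k) / n_test


@dataclass
class ChanceTest:
    t: float
    df: int
    p: float
    mean: float
    sensitivity: float | None = None
    specificity: float | None = None
    degenerate: bool = False


def evaluate_vs_chance(
    accuracies: np.ndarray,
    chance: float,
    confusion: "tuple[int, int, int, int] | None" = None,
    alternative: str = "two-sided",
) -> ChanceTest:
    """One-sample t test of fold accuracies against the corrected chance.

    ``confusion`` is (tn, fp, fn, tp) pooled counts with mind-wandering /
    "off" as the positive class; sensitivity and specificity derive from
    it.  Zero-variance accuracy vectors are flagged, not raised.
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least two accuracy values")
    mean = float(acc.mean())
    degenerate = bool(np.isclose(acc.std(ddof=1), 0.0))
    if degenerate:
        t = 0.0 if np.isclose(mean, chance) else np.inf * np.sign(mean - chance)
        p = 1.0 if np.isclose(mean, chance) else np.nan
    else:
        res = stats.ttest_1samp(acc, chance, alternative=alternative)
        t, p = float(res.statistic), float(res.pvalue)
    sens = spec = None
    if confusion is not None:
        tn, fp, fn, tp = confusion
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
    return ChanceTest(t=t, df=acc.size - 1, p=p, mean=mean,
                      sensitivity=sens, specificity=spec,
                      degenerate=degenerate)


# ---------------------------------------------------------------------------
# evaluation reports


@dataclass
class EvalReport:
    """Per-fold accuracies against the corrected chance level."""

    scheme: str
    kind: str  # 'lopocv', '10fold' or 'transfer'
    accuracies: np.ndarray
    fold_ids: list
    n_test: int
    chance: float
    test: ChanceTest
    confusion: tuple[int, int, int, int]  # tn, fp, fn, tp
    skipped: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def summary(self) -> str:
        c = self.test
        lines = [
            f"{self.scheme} classifier — {self.kind}",
            f"  folds: {len(self.accuracies)}   test trials: {self.n_test}",
            f"  mean accuracy {100 * self.mean_accuracy:.2f}%"
            f"   corrected chance {100 * self.chance:.2f}%",
            f"  one-sample t({c.df}) = {c.t:.2f}, p = {c.p:.4f}",
        ]
        if c.sensitivity is not None:
            lines.append(
                f"  sensitivity {c.sensitivity:.3f}"
                f"   specificity {c.specificity:.3f}"
            )
        if self.skipped:
            lines.append(f"  skipped folds: {self.skipped}")
        return "\n".join(lines)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    return np.array([tn, fp, fn, tp])


def _report(
    scheme: str,
    kind: str,
    accuracies: list,
    fold_ids: list,
    n_test: int,
    confusion: np.ndarray,
    skipped: list,
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> EvalReport:
    chance = corrected_chance_level(n_test, alpha)
    test = evaluate_vs_chance(np.asarray(accuracies), chance,
                              confusion=tuple(confusion),
                              alternative=alternative)
    return EvalReport(
        scheme=scheme, kind=kind, accuracies=np.asarray(accuracies),
        fold_ids=fold_ids, n_test=n_test, chance=chance, test=test,
        confusion=tuple(int(v) for v in confusion), skipped=skipped,
    )


@dataclass
class DecodingRun:
    """Everything one LOPOCV run produces for a single labeling scheme."""

    scheme: str
    lopocv: EvalReport
    inner_cv: EvalReport | None = None
    transfer: EvalReport | None = None
    models: list = field(default_factory=list)

    def summary(self) -> str:
        parts = [self.lopocv.summary()]
        if self.inner_cv is not None:
            parts.append(self.inner_cv.summary())
        if self.transfer is not None:
            parts.append(self.transfer.summary())
        return "\n\n".join(parts)


def _inner_cv_accuracies(
    X: np.ndarray, y: np.ndarray, seed: int, n_splits: int = 10
) -> tuple[list, list]:
    from sklearn.model_selection import StratifiedKFold

    counts = np.bincount(y)
    splits = int(min(n_splits, counts[counts > 0].min()))
    if splits < 2:
        return [], []
    skf = StratifiedKFold(n_splits=splits, shuffle=True, random_state=seed)
    accs, folds = [], []
    for j, (tr, te) in enumerate(skf.split(X, y)):
        prep = prepare_training(X[tr], y[tr], seed=seed + 7919 * (j + 1))
        model = train_svm(prep)
        accs.append(float((model.predict(X[te]) == y[te]).mean()))
        folds.append(j)
    return accs, folds


def run_lopocv(
    dataset: FeatureMatrix,
    scheme: str,
    seed: int,
    *,
    inner_cv: bool = True,
    transfer: bool = True,
    alpha: float = 0.05,
    feature_columns: np.ndarray | None = None,
) -> DecodingRun:
    """Leave-one-participant-out evaluation of one labeling scheme.

    Each outer fold re-estimates the scaler and the over-sampling on its
    own training sample (no leakage), validates by an inner 10-fold CV,
    predicts the held-out participant, and — when ``transfer`` is on —
    predicts the self-report-labeled SART trials across tasks.  The
    corrected chance level uses the pooled test-trial count.
    """
    trials = dataset.trials
    train_set = assign_labels(trials, scheme, task="VS")
    sart_set = None
    if transfer and (trials["task"] == "SART").any():
        try:
            sart_set = assign_labels(trials, "selfreport", task="SART")
        except ValueError:
            logger.info("no labelable SART trials; skipping transfer")
    values = dataset.values
    if feature_columns is not None:
        values = values[:, feature_columns]

    participants = sorted(pd.unique(train_set.participants))
    if len(participants) < 3:
        raise ValueError("leave-one-participant-out needs >= 3 participants")

    outer_acc, outer_ids, skipped, models = [], [], [], []
    outer_conf = np.zeros(4, dtype=int)
    inner_accs: list = []
    inner_ids: list = []
    trans_acc, trans_ids = [], []
    trans_conf = np.zeros(4, dtype=int)
    n_outer_test = 0

    for i, part in enumerate(participants):
        held = train_set.participants == part
        test = train_set.subset(held)
        train = train_set.subset(~held)
        if len(test) == 0:
            skipped.append(part)
            continue
        if np.unique(train.y).size < 2:
            skipped.append(part)
            continue
        fold_seed = seed + 104729 * (i + 1)
        Xtr = values[train.indices]
        prep = prepare_training(Xtr, train.y, seed=fold_seed)
        model = train_svm(prep, scheme=scheme)
        model.manifest["held_out"] = part
        model.manifest["seed"] = fold_seed
        models.append(model)

        pred = model.predict(values[test.indices])
        outer_acc.append(float((pred == test.y).mean()))
        outer_ids.append(part)
        outer_conf += _confusion(test.y, pred)
        n_outer_test += len(test)

        if inner_cv:
            accs, _ = _inner_cv_accuracies(Xtr, train.y, seed=fold_seed)
            inner_accs.extend(accs)
            inner_ids.extend([(part, j) for j in range(len(accs))])

        if sart_set is not None:
            spred = model.predict(values[sart_set.indices])
            trans_acc.append(float((spred == sart_set.y).mean()))
            trans_ids.append(part)
            trans_conf += _confusion(sart_set.y, spred)

    if not outer_acc:
        raise ValueError("no evaluable participants")

    run = DecodingRun(
        scheme=scheme,
        lopocv=_report(scheme, "lopocv", outer_acc, outer_ids, n_outer_test,
                       outer_conf, skipped, alpha=alpha),
        models=models,
    )
    if inner_cv and len(inner_accs) >= 2:
        run.inner_cv = _report(scheme, "10fold", inner_accs, inner_ids,
                               n_outer_test, np.zeros(4, dtype=int), [],
                               alpha=alpha)
    if sart_set is not None and trans_acc:
        run.transfer = _report(scheme, "transfer", trans_acc, trans_ids,
                               len(sart_set), trans_conf, [], alpha=alpha)
    return run


def cross_task_predict(
    model: TrainedModel,
    dataset: FeatureMatrix,
    sart_set: LabeledSet,
    alpha: float = 0.05,
) -> EvalReport:
    """Accuracy of a visual-search-trained model on SART self-report trials."""
    if sart_set.scheme != "selfreport":
        raise ValueError("across-task test labels must be self-report")
    y_pred = model.predict(dataset.values[sart_set.indices])
    conf = _confusion(sart_set.y, y_pred)
    accs, ids = [], []
    for part in sorted(pd.unique(sart_set.participants)):
        mask = sart_set.participants == part
        accs.append(float((y_pred[mask] == sart_set.y[mask]).mean()))
        ids.append(part)
    return _report(model.scheme, "transfer", accs, ids, len(sart_set), conf, [],
                   alpha=alpha)
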