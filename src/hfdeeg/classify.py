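"""Transferable pairwise classification of participant groups from HFD features.

The classifier is a linear soft-margin SVM in its nu parameterisation
(nu-SVC): nu in (0, 1] upper-bounds the fraction of margin errors and
lower-bounds the fraction of support vectors.  Input vectors are per-trial
HFD features from a subset of channels at one window offset; the channel
subset is found by greedy forward selection, a wrapper method that starts
from the empty set, adds the channel with the highest inner cross-validated
accuracy, and keeps adding the best further channel until no candidate
strictly improves accuracy (ties break in montage order).

Generalisation to unseen participants is estimated with nested
leave-one-subject-out cross-validation: the outer loop holds out every
participant once; within each outer training set, the hyper-parameters
(window offset, nu) are grid-searched with inner leave-one-subject-out
accuracy as the criterion, the channel subset being re-selected greedily at
every grid point.  Feature standardisation is always fit on training data
only.  Per-trial predictions on held-out participants are summarised as
accuracy mean +/- sd across participants, sensitivity, specificity, and the
percentage of participants whose majority-voted prediction is correct.

Transfer evaluation freezes channels and offset to values learned on a
source cohort and re-optimises only nu on the target cohort — the test of
whether markers learned on chronic pain transfer to subacute cohorts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import NuSVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ClassifierConfig",
    "ChannelSelection",
    "EvalReport",
    "trial_vectors",
    "GreedyChannelSelector",
    "greedy_select",
    "nested_loso_evaluate",
    "transfer_evaluate",
    "majority_vote",
]

logger = logging.getLogger(__name__)

_DEFAULT_NU_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.025), 3))


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyper-parameter grids and preprocessing switches.

    The default nu grid is the 0.025 lattice over (0, 0.95]; the offset grid
    spans the four analysis windows.  ``standardize`` z-scores features with
    statistics from the training split only.
    """

    nu_grid: tuple[float, ...] = _DEFAULT_NU_GRID
    offset_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    kernel: str = "linear"
    standardize: bool = True
    svc_tol: float = 1e-3

    def __post_init__(self) -> None:
        if not self.nu_grid or not self.offset_grid:
            raise ValueError("nu_grid and offset_grid must be non-empty")
        if any(not 0.0 < nu <= 1.0 for nu in self.nu_grid):
            raise ValueError("every nu must lie in (0, 1]")


@dataclass(frozen=True)
class ChannelSelection:
    """Result of greedy forward channel selection."""

    channels: tuple[str, ...]
    accuracy_trace: tuple[float, ...]
    halting_reason: str

    @property
    def accuracy(self) -> float:
        return self.accuracy_trace[-1]


@dataclass
class EvalReport:
    """Held-out performance of the nested LOSO evaluation."""

    task: str
    accuracy_mean: float        # mean per-trial accuracy across participants
    accuracy_sd: float
    sensitivity: float
    specificity: float
    participants_correct: float  # percentage, majority vote
    positive_label: str
    fold_winners: list = field(default_factory=list)
    modal_config: dict = field(default_factory=dict)
    predictions: pd.DataFrame | None = field(default=None, repr=False)

    def to_jsonable(self) -> dict:
        return {
            "task": self.task,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "participants_correct": self.participants_correct,
            "positive_label": self.positive_label,
            "fold_winners": [
                {
                    "held_out": w["held_out"],
                    "offset": w["offset"],
                    "channels": list(w["channels"]),
                    "nu": w["nu"],
                    "inner_accuracy": w["inner_accuracy"],
                }
                for w in self.fold_winners
            ],
            "modal_config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.modal_config.items()
            },
        }


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def trial_vectors(
    features: pd.DataFrame,
    task: str,
    channels: list[str],
    offset: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial design matrix for one task and window offset.

    Returns ``(X, y, participants)``: one row per trial, columns ordered by
    ``channels``, labels the group membership.  Trials with any missing
    feature are dropped (count logged).
    """
    sub = features[
        (features["task"] == task) & (features["window_offset"] == offset)
    ]
    if sub.empty:
        raise ValueError(f"no rows for task={task!r}, offset={offset}")
    missing = [ch for ch in channels if ch not in set(sub["channel"])]
    if missing:
        raise ValueError(f"channels not in feature table: {missing}")
    wide = sub.pivot_table(
        index=["group", "participant", "trial"],
        columns="channel",
        values="hfd",
        aggfunc="first",
    )[list(channels)]
    n_before = len(wide)
    wide = wide.dropna()
    if len(wide) < n_before:
        logger.warning("trial_vectors: dropped %d trials with missing features",
                       n_before - len(wide))
    idx = wide.index.to_frame(index=False)
    return (
        wide.to_numpy(),
        idx["group"].to_numpy(),
        idx["participant"].to_numpy(),
    )


def _loso_splits(participants: np.ndarray):
    """Leave-one-participant-out splits as boolean masks, in first-appearance
    order of participants."""
    order = pd.unique(participants)
    for p in order:
        test = participants == p
        yield p, ~test, test


def _fit_svc(x_tr, y_tr, nu, tol, standardize):
    if standardize:
        mu = x_tr.mean(axis=0)
        sd = x_tr.std(axis=0)
        sd = np.where(sd == 0.0, 1.0, sd)
    else:
        mu = np.zeros(x_tr.shape[1])
        sd = np.ones(x_tr.shape[1])
    clf = NuSVC(nu=nu, kernel="linear", tol=tol)
    clf.fit((x_tr - mu) / sd, y_tr)
    return clf, mu, sd


def _cv_accuracy(x, y, participants, nu, tol, standardize, audit=None):
    """Mean leave-one-participant-out accuracy (participants weighted equally).

    Folds where the nu-SVC is infeasible (or the training split degenerate)
    score 0 so such configurations can never win the grid search.
    """
    accs = []
    for held, tr, te in _loso_splits(participants):
        if audit is not None:
            audit.append((set(pd.unique(participants[tr])), held))
        if len(np.unique(y[tr])) < 2:
            accs.append(0.0)
            continue
        try:
            clf, mu, sd = _fit_svc(x[tr], y[tr], nu, tol, standardize)
        except ValueError:
            accs.append(0.0)
            continue
        pred = clf.predict((x[te] - mu) / sd)
        accs.append(float(np.mean(pred == y[te])))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# greedy forward channel selection
# ---------------------------------------------------------------------------

class GreedyChannelSelector(BaseEstimator, ClassifierMixin):
    """Greedy forward channel selection wrapped around a linear nu-SVC.

    scikit-learn-style estimator: ``fit(X, y, groups=participants)`` where
    the columns of ``X`` are candidate channels (one feature per channel at a
    fixed window offset) and ``groups`` identifies the participant of each
    trial for the inner leave-one-participant-out accuracy criterion.

    Selection starts empty, adds the single best channel, then repeatedly
    adds the candidate that strictly improves inner-CV accuracy; it halts
    when no candidate improves.  Ties break in column (montage) order.

    Fitted attributes: ``selected_idx_``, ``selected_channels_``,
    ``accuracy_trace_``, ``halting_reason_``, and the final classifier
    refitted on all training trials over the selected columns.
    """

    def __init__(self, nu: float = 0.5, standardize: bool = True,
                 tol: float = 1e-3, channel_names: list[str] | None = None):
        self.nu = nu
        self.standardize = standardize
        self.tol = tol
        self.channel_names = channel_names

    def fit(self, X, y, groups=None, audit=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if groups is None:
            raise ValueError("groups (participant ids) are required")
        groups = np.asarray(groups)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training set contains a single class")
        n_chan = X.shape[1]
        names = (list(self.channel_names) if self.channel_names is not None
                 else [str(i) for i in range(n_chan)])
        if len(names) != n_chan:
            raise ValueError("channel_names length must match n_columns")

        selected: list[int] = []
        trace: list[float] = []
        best_acc = -np.inf
        reason = "no further channel improves accuracy"
        while len(selected) < n_chan:
            cand_best, cand_acc = None, best_acc
            for j in range(n_chan):
                if j in selected:
                    continue
                cols = selected + [j]
                acc = _cv_accuracy(X[:, cols], y, groups, self.nu, self.tol,
                                   self.standardize, audit=audit)
                if acc > cand_acc:  # strict improvement; ties keep first
                    cand_best, cand_acc = j, acc
            if cand_best is None:
                break
            selected.append(cand_best)
            best_acc = cand_acc
            trace.append(best_acc)
        else:
            reason = "all channels selected"

        self.classes_ = classes
        self.selected_idx_ = tuple(selected)
        self.selected_channels_ = tuple(names[j] for j in selected)
        self.accuracy_trace_ = tuple(trace)
        self.halting_reason_ = reason
        clf, mu, sd = _fit_svc(X[:, list(selected)], y, self.nu, self.tol,
                               self.standardize)
        self.estimator_, self.scale_mean_, self.scale_sd_ = clf, mu, sd
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)[:, list(self.selected_idx_)]
        return self.estimator_.predict((X - self.scale_mean_) / self.scale_sd_)

    @property
    def selection_(self) -> ChannelSelection:
        check_is_fitted(self, "estimator_")
        return ChannelSelection(
            channels=self.selected_channels_,
            accuracy_trace=self.accuracy_trace_,
            halting_reason=self.halting_reason_,
        )


def greedy_select(
    train_features: pd.DataFrame,
    task: str,
    offset: float,
    nu: float,
    channels: list[str] | None = None,
    config: ClassifierConfig | None = None,
) -> ChannelSelection:
    """Greedy forward channel selection on a training feature table.

    Candidate ``channels`` default to every channel in the table, in table
    (montage) order.  Requires at least two participants per class.
    """
    config = config or ClassifierConfig()
    if channels is None:
        channels = list(pd.unique(train_features["channel"]))
    x, y, parts = trial_vectors(train_features, task, channels, offset)
    for cls in np.unique(y):
        if len(pd.unique(parts[y == cls])) < 2:
            raise ValueError(
                f"class {cls!r} needs at least two participants for inner CV"
            )
    sel = GreedyChannelSelector(nu=nu, standardize=config.standardize,
                                tol=config.svc_tol, channel_names=channels)
    sel.fit(x, y, groups=parts)
    return sel.selection_


# ---------------------------------------------------------------------------
# nested LOSO evaluation
# ---------------------------------------------------------------------------

def majority_vote(predictions: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Participant-level predictions by majority vote.

    ``predictions`` needs columns participant, true, predicted.  The modal
    predicted class wins; an exact tie counts as incorrect (conservative).
    Returns the per-participant frame and the percentage correct.
    """
    rows = []
    for participant, grp in predictions.groupby("participant", sort=False):
        counts = Counter(grp["predicted"])
        ranked = counts.most_common()
        tie = len(ranked) > 1 and ranked[0][1] == ranked[1][1]
        voted = None if tie else ranked[0][0]
        true = grp["true"].iloc[0]
        rows.append(
            {"participant": participant, "true": true, "predicted": voted,
             "correct": (voted == true) and not tie}
        )
    frame = pd.DataFrame(rows)
    return frame, 100.0 * float(frame["correct"].mean())


def _summarise(task, predictions, fold_winners, positive_label) -> EvalReport:
    per_part = predictions.groupby("participant", sort=False).apply(
        lambda g: float(np.mean(g["predicted"] == g["true"])),
        include_groups=False,
    )
    labels = pd.unique(predictions["true"])
    if positive_label is None:
        positive_label = labels[0]
    pos = predictions["true"] == positive_label
    sens = float(np.mean(predictions.loc[pos, "predicted"] == positive_label))
    spec = float(np.mean(predictions.loc[~pos, "predicted"] != positive_label))
    _, pct = majority_vote(predictions)
    keys = [(w["offset"], w["channels"], w["nu"]) for w in fold_winners]
    modal = Counter(keys).most_common(1)[0][0] if keys else None
    modal_config = (
        {"offset": modal[0], "channels": modal[1], "nu": modal[2]}
        if modal else {}
    )
    return EvalReport(
        task=task,
        accuracy_mean=float(per_part.mean()),
        accuracy_sd=float(per_part.std(ddof=1)) if len(per_part) > 1 else 0.0,
        sensitivity=sens,
        specificity=spec,
        participants_correct=pct,
        positive_label=str(positive_label),
        fold_winners=fold_winners,
        modal_config=modal_config,
        predictions=predictions,
    )


def _grid_matrices(features, task, offsets, channels):
    """Design matrix per offset, rows aligned across offsets where possible."""
    mats = {}
    for off in offsets:
        mats[off] = trial_vectors(features, task, channels, off)
    return mats


def nested_loso_evaluate(
    features: pd.DataFrame,
    task: str,
    config: ClassifierConfig | None = None,
    channels: list[str] | None = None,
    positive_label: str | None = None,
    audit: list | None = None,
) -> EvalReport:
    """Nested leave-one-subject-out evaluation with full hyper-parameter search.

    Outer loop: hold out each participant once.  Inner loop, per outer fold:
    grid over (offset, nu), greedy channel re-selection at every grid point,
    inner leave-one-participant-out accuracy as the criterion (grid-order
    tie-break).  The winning configuration is refitted on the full outer
    training set and applied to the held-out participant's trials.

    ``audit``, when given, collects (inner_train_participants, inner_held_out,
    outer_held_out) triples so leakage can be checked externally.
    """
    config = config or ClassifierConfig()
    if channels is None:
        channels = list(pd.unique(features["channel"]))
    mats = _grid_matrices(features, task, config.offset_grid, channels)
    _, y0, parts0 = mats[config.offset_grid[0]]
    if len(np.unique(y0)) != 2:
        raise ValueError("nested LOSO evaluation requires exactly two groups")
    all_parts = list(pd.unique(parts0))

    pred_rows = []
    fold_winners = []
    for held_out in all_parts:
        best = None  # (inner_acc, grid_rank, offset, nu, channels_idx)
        for g_rank, (off, nu) in enumerate(
            (o, n) for o in config.offset_grid for n in config.nu_grid
        ):
            x, y, parts = mats[off]
            tr = parts != held_out
            fold_audit = None
            if audit is not None:
                fold_audit = []
            sel = GreedyChannelSelector(
                nu=nu, standardize=config.standardize, tol=config.svc_tol,
                channel_names=channels,
            )
            sel.fit(x[tr], y[tr], groups=parts[tr], audit=fold_audit)
            if audit is not None:
                audit.extend(
                    (train_set, inner_held, held_out)
                    for train_set, inner_held in fold_audit
                )
            acc = sel.accuracy_trace_[-1]
            if best is None or acc > best[0]:
                best = (acc, g_rank, off, nu, sel)
        acc, _, off, nu, sel = best
        x, y, parts = mats[off]
        te = parts == held_out
        pred = sel.predict(x[te])
        for t_i, (p, yy) in enumerate(zip(pred, y[te])):
            pred_rows.append(
                {"participant": held_out, "trial": t_i, "true": yy,
                 "predicted": p}
            )
        fold_winners.append(
            {"held_out": held_out, "offset": off, "nu": nu,
             "channels": sel.selected_channels_, "inner_accuracy": acc}
        )
    predictions = pd.DataFrame(pred_rows)
    return _summarise(task, predictions, fold_winners, positive_label)


def transfer_evaluate(
    target_features: pd.DataFrame,
    task: str,
    source_channels: list[str],
    source_offset: float,
    config: ClassifierConfig | None = None,
    positive_label: str | None = None,
) -> EvalReport:
    """Evaluate with channels and offset frozen to source-cohort values.

    Only nu is re-optimised (inner leave-one-participant-out accuracy) in
    each outer fold; channels/offset come from the source study.
    """
    config = config or ClassifierConfig()
    x, y, parts = trial_vectors(target_features, task, list(source_channels),
                                source_offset)
    if len(np.unique(y)) != 2:
        raise ValueError("transfer evaluation requires exactly two groups")
    all_parts = list(pd.unique(parts))
    pred_rows = []
    fold_winners = []
    for held_out in all_parts:
        tr = parts != held_out
        best = None
        for nu in config.nu_grid:
            acc = _cv_accuracy(x[tr], y[tr], parts[tr], nu, config.svc_tol,
                               config.standardize)
            if best is None or acc > best[0]:
                best = (acc, nu)
        acc, nu = best
        try:
            clf, mu, sd = _fit_svc(x[tr], y[tr], nu, config.svc_tol,
                                   config.standardize)
        except ValueError:
            logger.warning("transfer fold %s: infeasible nu=%s", held_out, nu)
            continue
        pred = clf.predict((x[~tr] - mu) / sd)
        for t_i, (p, yy) in enumerate(zip(pred, y[~tr])):
            pred_rows.append(
                {"participant": held_out, "trial": t_i, "true": yy,
                 "predicted": p}
            )
        fold_winners.append(
            {"held_out": held_out, "offset": source_offset, "nu": nu,
             "channels": tuple(source_channels), "inner_accuracy": acc}
        )
    predictions = pd.DataFrame(pred_rows)
    return _summarise(task, predictions, fold_winners, positive_label)
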