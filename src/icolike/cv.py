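"""Double cross-validation machinery: fold plans, outer predictions, metrics.

Outer prediction errors are the raw material of the outlier diagnostic, so
the fold plans must be reproducible and must stay *aligned* when a candidate
sample is removed: every remaining sample keeps the fold index it had in the
full-data plan.  ``restrict_fold_plan`` provides exactly that, and
``force_always_train`` pins a sample into every training partition without
disturbing the other assignments.

The "double" in double cross-validation means hyperparameter selection
happens inside each outer training partition only.  For the GPR backend the
marginal-likelihood maximisation performed within each fold fit *is* that
inner selection; no separate inner grid search is added.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .backends import BackendConfig, make_backend
from .dataset import Dataset
from .exceptions import FitFailureError, InputError

__all__ = [
    "FoldPlan",
    "make_fold_plan",
    "restrict_fold_plan",
    "force_always_train",
    "OuterPredictions",
    "run_outer_cv",
    "CVMetrics",
    "compute_metrics",
    "CVSettings",
]


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of samples to outer folds.

    ``assignment`` maps each held-out-able sample id to a fold index in
    ``0..k-1``; ids in ``always_train`` are never held out.  With ``k`` equal
    to the number of assigned samples every fold is a singleton (leave-one-out).
    """

    assignment: dict[str, int]
    k: int
    seed: int
    always_train: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))
        object.__setattr__(self, "always_train", frozenset(self.always_train))
        overlap = self.always_train & set(self.assignment)
        if overlap:
            raise InputError(
                f"samples both assigned and always_train: {sorted(overlap)}"
            )
        bad = [f for f in self.assignment.values() if not 0 <= f < self.k]
        if bad:
            raise InputError(f"fold indices outside 0..{self.k - 1}: {bad}")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.assignment) | self.always_train

    @property
    def is_loo(self) -> bool:
        return self.k == len(self.assignment)

    def fold_members(self, fold: int) -> tuple[str, ...]:
        return tuple(
            sid for sid, f in self.assignment.items() if f == fold
        )

    def occupied_folds(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.assignment.values())))

    def partition_key(self) -> tuple:
        """Canonical identity of the induced train/test partitions.

        Fold labels themselves do not matter for the predictions a plan
        produces, only which samples are held out together and which are
        pinned to training — this key ignores labels, so e.g. all
        leave-one-out plans over the same samples share a key.
        """
        groups = tuple(
            sorted(tuple(sorted(self.fold_members(f)))
                   for f in self.occupied_folds())
        )
        return (groups, tuple(sorted(self.always_train)))

    def digest(self) -> str:
        """Short hash of the full assignment, for run logs."""
        payload = repr((sorted(self.assignment.items()), self.k,
                        sorted(self.always_train))).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def make_fold_plan(sample_ids, k, seed: int = 0,
                   always_train=frozenset()) -> FoldPlan:
    """Build a reproducible outer fold plan.

    Samples (minus ``always_train``) are shuffled with ``seed`` and dealt
    round-robin into ``k`` folds, so fold sizes differ by at most one.
    ``k`` equal to the number of assignable samples gives leave-one-out.
    """
    ids = [str(i) for i in sample_ids]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate sample ids in fold plan request")
    always = frozenset(str(i) for i in always_train)
    unknown = always - set(ids)
    if unknown:
        raise InputError(f"always_train ids not in sample_ids: {sorted(unknown)}")
    assignable = [i for i in ids if i not in always]
    n = len(assignable)
    if isinstance(k, str):
        if k != "loo":
            raise InputError(f"k must be an integer or 'loo', got {k!r}")
        k = n
    k = int(k)
    if k > n:
        raise InputError(f"k={k} exceeds {n} assignable samples")
    if k < 2 and k != n:
        raise InputError(f"k must be >= 2 (or equal the sample count), got {k}")
    if n == 0:
        raise InputError("no assignable samples")
    rng = np.random.default_rng(seed)
    order = list(np.array(assignable, dtype=object)[rng.permutation(n)])
    assignment = {sid: pos % k for pos, sid in enumerate(order)}
    return FoldPlan(assignment=assignment, k=k, seed=int(seed),
                    always_train=always)


def restrict_fold_plan(plan: FoldPlan, excluded_id: str) -> FoldPlan:
    """Drop one sample; everyone else keeps their fold index."""
    excluded_id = str(excluded_id)
    if excluded_id in plan.assignment:
        assignment = {s: f for s, f in plan.assignment.items()
                      if s != excluded_id}
        return FoldPlan(assignment=assignment, k=plan.k, seed=plan.seed,
                        always_train=plan.always_train)
    if excluded_id in plan.always_train:
        return FoldPlan(assignment=dict(plan.assignment), k=plan.k,
                        seed=plan.seed,
                        always_train=plan.always_train - {excluded_id})
    raise InputError(f"sample {excluded_id!r} not in fold plan")


def force_always_train(plan: FoldPlan, sample_id: str) -> FoldPlan:
    """Move one sample into every training partition; others untouched."""
    sample_id = str(sample_id)
    if sample_id in plan.always_train:
        return plan
    if sample_id not in plan.assignment:
        raise InputError(f"sample {sample_id!r} not in fold plan")
    assignment = {s: f for s, f in plan.assignment.items() if s != sample_id}
    return FoldPlan(assignment=assignment, k=plan.k, seed=plan.seed,
                    always_train=plan.always_train | {sample_id})


@dataclass(frozen=True)
class OuterPredictions:
    """Cross-validated prediction and absolute error per held-out sample."""

    predicted: dict[str, float]
    abs_error: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.predicted) != set(self.abs_error):
            raise InputError("predicted and abs_error cover different samples")

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self.predicted)

    def errors_for(self, subset) -> np.ndarray:
        return np.array([self.abs_error[str(s)] for s in subset], dtype=float)


def run_outer_cv(dataset: Dataset, plan: FoldPlan,
                 backend: BackendConfig | None = None) -> OuterPredictions:
    """Run the outer loop: fit on each training partition, predict its fold.

    Each fold's model is fitted on every plan-universe sample *not* in that
    fold (always-train samples included), with backend hyperparameter
    selection happening inside that training partition only.
    """
    backend = backend or BackendConfig()
    universe = plan.universe
    missing = universe - set(dataset.ids)
    if missing:
        raise InputError(f"plan references unknown samples: {sorted(missing)}")
    engine = make_backend(backend)
    id_to_idx = {sid: j for j, sid in enumerate(dataset.ids)}
    predicted: dict[str, float] = {}
    abs_error: dict[str, float] = {}
    for fold in plan.occupied_folds():
        test_ids = plan.fold_members(fold)
        train_ids = [s for s in dataset.ids
                     if s in universe and s not in test_ids]
        if not train_ids:
            raise InputError(f"fold {fold} leaves an empty training partition")
        tr = [id_to_idx[s] for s in train_ids]
        te = [id_to_idx[s] for s in test_ids]
        try:
            handle = engine.fit(dataset.X[tr], dataset.y[tr])
        except FitFailureError as exc:
            raise FitFailureError(str(exc), stage="outer_cv",
                                  fold=fold) from exc
        yhat = handle.predict(dataset.X[te])
        for sid, idx, pred in zip(test_ids, te, yhat):
            predicted[sid] = float(pred)
            abs_error[sid] = abs(float(dataset.y[idx]) - float(pred))
    return OuterPredictions(predicted=predicted, abs_error=abs_error)


@dataclass(frozen=True)
class CVMetrics:
    """MAE and coefficient of determination over a stated sample subset."""

    mae: float
    r2: float  # NaN when the subset has zero target variance
    n_evaluated: int


def compute_metrics(predictions: OuterPredictions, dataset: Dataset,
                    subset=None) -> CVMetrics:
    """MAE and R^2 of the outer predictions over exactly ``subset``.

    R^2 uses the subset's own target mean.  A subset with zero target
    variance has no defined R^2; it is reported as NaN while MAE remains
    valid.
    """
    ids = sorted(predictions.ids) if subset is None else [str(s) for s in subset]
    if not ids:
        raise InputError("empty evaluation subset")
    missing = set(ids) - predictions.ids
    if missing:
        raise InputError(f"subset samples without predictions: {sorted(missing)}")
    y = np.array([dataset.y_of(s) for s in ids])
    yhat = np.array([predictions.predicted[s] for s in ids])
    mae = float(np.mean(np.abs(y - yhat)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return CVMetrics(mae=mae, r2=r2, n_evaluated=len(ids))


@dataclass(frozen=True)
class CVSettings:
    """Outer-loop settings: fold count (or "loo") and the split seed."""

    outer_k: int | str = "loo"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.outer_k, str) and self.outer_k != "loo":
            raise InputError(f"outer_k must be an integer or 'loo', "
                             f"got {self.outer_k!r}")

    def resolve_k(self, n_samples: int) -> int:
        return n_samples if self.outer_k == "loo" else int(self.outer_k)

    @property
    def is_loo_request(self) -> bool:
        return self.outer_k == "loo"
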