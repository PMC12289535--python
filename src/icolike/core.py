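"""ICO-likeness: scoring and classifying regression outlier candidates.

A sample flagged as an outlier by its cross-validated prediction error can
be one of two very different things.  A *consistent outlier* (CO) sits on —
or on a distant extension of — the same x–y relationship as the rest of the
data: a better model or more data could explain it.  An *inconsistent
outlier* (ICO) has a y that the current features cannot explain under any
model consistent with the other samples: it signals an erroneous record or
a missing descriptor, and keeping it in training actively degrades the
predictions of everything else.

The diagnostic quantifies exactly that degradation.  For a candidate A:

    ICO-likeness(A) = MAE_wOS - MAE_woOS

where both mean absolute errors are taken over the *other* samples' outer
cross-validation predictions — MAE_wOS from a run in which A participates
in every training partition, MAE_woOS from an aligned run with A removed.
A large positive value means A's presence in training hurts everyone else:
an ICO signature.  Values near zero (or negative) mean A is merely extreme:
a CO.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .backends import BackendConfig
from .cv import (
    CVSettings,
    FoldPlan,
    OuterPredictions,
    compute_metrics,
    force_always_train,
    make_fold_plan,
    restrict_fold_plan,
    run_outer_cv,
)
from .dataset import Dataset
from .exceptions import FitFailureError, InputError

__all__ = [
    "CandidateList",
    "rank_by_abs_error",
    "ICORecord",
    "ico_likeness",
    "ClassificationRule",
    "classify_records",
    "multi_outlier_screen",
    "CVCache",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateList:
    """Candidates ordered by outer absolute error (descending; ties by id)."""

    entries: tuple[tuple[str, float], ...]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.entries)

    def abs_error_of(self, sample_id: str) -> float:
        for sid, err in self.entries:
            if sid == str(sample_id):
                return err
        raise InputError(f"{sample_id!r} not in candidate list")

    def __len__(self) -> int:
        return len(self.entries)


def rank_by_abs_error(predictions: OuterPredictions,
                      top_k: int | str = "all") -> CandidateList:
    """Select the samples whose outer absolute errors are largest.

    Ties are broken by ascending sample id so the ranking is deterministic.
    """
    if not predictions.ids:
        raise InputError("no outer predictions to rank")
    if top_k != "all":
        top_k = int(top_k)
        if top_k < 1:
            raise InputError(f"top_k must be >= 1 or 'all', got {top_k}")
    ordered = sorted(predictions.abs_error.items(),
                     key=lambda kv: (-kv[1], kv[0]))
    if top_k != "all":
        ordered = ordered[:top_k]
    return CandidateList(entries=tuple((s, float(e)) for s, e in ordered))


@dataclass(frozen=True)
class ICORecord:
    """One candidate's scores: the two MAEs, their difference, and a label.

    ``mae_wos`` and ``mae_woos`` are computed over the identical set of
    non-candidate samples, so ``ico_likeness = mae_wos - mae_woos`` compares
    like with like.  ``abs_error`` is the candidate's own outer error from
    the full-data cross-validation (NaN if that run never held it out).
    """

    candidate_id: str
    mae_wos: float
    mae_woos: float
    ico_likeness: float
    abs_error: float = float("nan")
    label: str = "unlabeled"  # one of {"ICO", "CO", "unlabeled"}


class CVCache(dict):
    """Memo of outer-CV runs keyed by (data content, partitions, backend).

    Fold labels are ignored in the key — only the induced train/test
    partitions matter for the predictions — so e.g. the without-candidate
    leave-one-out run over a shared base dataset is computed once even when
    candidates were appended in different orders.
    """

    hits = 0

    def run(self, dataset: Dataset, plan: FoldPlan,
            backend: BackendConfig) -> OuterPredictions:
        key = (dataset.content_key(), plan.partition_key(), backend.key())
        if key in self:
            self.hits += 1
            return self[key]
        preds = run_outer_cv(dataset, plan, backend)
        self[key] = preds
        return preds


def _run_cv(dataset, plan, backend, cache: CVCache | None):
    if cache is not None:
        return cache.run(dataset, plan, backend)
    return run_outer_cv(dataset, plan, backend)


def ico_likeness(dataset: Dataset, candidate_id: str,
                 backend: BackendConfig | None = None,
                 cv: CVSettings | None = None,
                 *,
                 plan: FoldPlan | None = None,
                 full_predictions: OuterPredictions | None = None,
                 cache: CVCache | None = None) -> ICORecord:
    """Score one candidate by the aligned with/without cross-validation pair.

    The procedure, for candidate A:

    1. Outer CV on the full dataset with A in every training partition.
       Under leave-one-out A is additionally held out once (its own error
       is recorded but never enters the MAEs); with k < n folds A is pinned
       into training and receives no outer prediction.
    2. Outer CV on the dataset minus A under the *restricted* fold plan, so
       every other sample keeps its fold from step 1.
    3. MAE_wOS: mean absolute error over all non-A samples from step 1.
    4. MAE_woOS: mean absolute error over the same ids from step 2.
    5. ICO-likeness = MAE_wOS - MAE_woOS.

    Parameters
    ----------
    plan, full_predictions, cache
        Optional precomputed artifacts.  ``plan`` must cover the full
        dataset; ``full_predictions`` (leave-one-out only) is the step-1
        run, shared across candidates; ``cache`` memoises CV runs across
        repeated calls (the without-candidate run of a multi-outlier screen,
        for instance, is identical for every candidate).
    """
    backend = backend or BackendConfig()
    cv = cv or CVSettings()
    candidate_id = str(candidate_id)
    if candidate_id not in dataset.ids:
        raise InputError(f"candidate {candidate_id!r} not in dataset")
    n = dataset.n_samples
    k = cv.resolve_k(n)
    if plan is None:
        plan = make_fold_plan(dataset.ids, k, cv.seed)
    if plan.universe != frozenset(dataset.ids):
        raise InputError("fold plan does not cover the dataset")
    loo = plan.is_loo

    other_ids = tuple(s for s in dataset.ids if s != candidate_id)

    # step 1: with the candidate available to every training partition
    if loo:
        if full_predictions is None:
            full_predictions = _run_cv(dataset, plan, backend, cache)
        preds_with = full_predictions
        own_error = preds_with.abs_error.get(candidate_id, float("nan"))
    else:
        plan_with = force_always_train(plan, candidate_id)
        try:
            preds_with = _run_cv(dataset, plan_with, backend, cache)
        except FitFailureError as exc:
            raise FitFailureError(str(exc), stage="with_candidate") from exc
        own_error = float("nan")

    # step 2: aligned run without the candidate
    reduced = dataset.drop(candidate_id)
    plan_without = restrict_fold_plan(plan, candidate_id)
    try:
        preds_without = _run_cv(reduced, plan_without, backend, cache)
    except FitFailureError as exc:
        raise FitFailureError(str(exc), stage="without_candidate") from exc

    eval_with = sorted(set(other_ids) & preds_with.ids)
    eval_without = sorted(preds_without.ids)
    if eval_with != eval_without:
        raise InputError(
            "with/without runs evaluated different samples: "
            f"{sorted(set(eval_with) ^ set(eval_without))}"
        )

    mae_wos = compute_metrics(preds_with, dataset, eval_with).mae
    mae_woos = compute_metrics(preds_without, reduced, eval_without).mae
    return ICORecord(
        candidate_id=candidate_id,
        mae_wos=mae_wos,
        mae_woos=mae_woos,
        ico_likeness=mae_wos - mae_woos,
        abs_error=float(own_error),
    )


@dataclass(frozen=True)
class ClassificationRule:
    """How to split candidate scores into ICO vs CO.

    ``robust_z`` (default): a record is ICO when its ICO-likeness exceeds
    ``median + multiplier * MAD`` of all supplied records' scores, with the
    MAD the unscaled median absolute deviation from the median.  Robust on
    purpose: the handful of very large scores are exactly what we are
    hunting, and they must not inflate the reference level.

    ``absolute_threshold``: ICO when the score exceeds a fixed ``threshold``.
    """

    method: str = "robust_z"
    multiplier: float = 3.0
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ("robust_z", "absolute_threshold"):
            raise InputError(f"unknown classification method {self.method!r}")
        if not math.isfinite(self.multiplier) or self.multiplier <= 0:
            raise InputError(f"multiplier must be positive, got {self.multiplier}")
        if not math.isfinite(self.threshold):
            raise InputError("threshold must be finite")

    def cutoff(self, values: np.ndarray) -> float:
        if self.method == "absolute_threshold":
            return float(self.threshold)
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med)))
        return med + self.multiplier * mad


def classify_records(records, rule: ClassificationRule | None = None):
    """Label each record ICO or CO; input order is preserved.

    With the robust_z rule the reference population is the supplied records
    themselves, so scoring *all* samples (not just the flagged ones) gives
    the most faithful reference level for "normal" scores.
    """
    rule = rule or ClassificationRule()
    records = list(records)
    if rule.method == "robust_z" and len(records) < 3:
        raise InputError(
            f"robust_z needs >= 3 records, got {len(records)}; "
            "use an absolute_threshold rule for fewer"
        )
    if not records:
        raise InputError("no records to classify")
    values = np.array([r.ico_likeness for r in records], dtype=float)
    cut = rule.cutoff(values)
    if rule.method == "robust_z" and np.all(values == values[0]):
        logger.info("all ICO-likeness values identical (MAD=0); labelling all CO")
    return [replace(r, label="ICO" if r.ico_likeness > cut else "CO")
            for r in records]


def multi_outlier_screen(dataset: Dataset, outlier_ids,
                         backend: BackendConfig | None = None,
                         cv: CVSettings | None = None,
                         *, cache: CVCache | None = None):
    """Score several pre-detected outliers, one at a time against a clean base.

    All flagged outliers are removed first; each is then added back alone and
    scored, so no outlier contaminates another's reference cross-validation.
    Returns one (unlabeled) record per outlier, in sorted-id order.
    """
    outlier_ids = sorted(str(o) for o in outlier_ids)
    if not outlier_ids:
        raise InputError("empty outlier set")
    unknown = set(outlier_ids) - set(dataset.ids)
    if unknown:
        raise InputError(f"outlier ids not in dataset: {sorted(unknown)}")
    base_ids = [s for s in dataset.ids if s not in set(outlier_ids)]
    cv = cv or CVSettings()
    if cache is None:
        cache = CVCache()  # the without-candidate run is shared across outliers
    records = []
    for oid in outlier_ids:
        sub = dataset.subset(base_ids + [oid])
        records.append(ico_likeness(sub, oid, backend, cv, cache=cache))
    return records
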