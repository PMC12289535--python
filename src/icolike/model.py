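"""Model/Results facade: fit the outlier diagnostic to a dataset.

Follows the two-object convention of statistical modelling packages: an
:class:`ICOLikeness` model is built from data plus settings, and its
:meth:`~ICOLikeness.fit` returns an :class:`ICOResults` carrying the
cross-validation metrics, the per-candidate scores with CO/ICO labels, a
``summary()`` table and a diagnostic plot.

Example
-------
>>> from icolike import ICOLikeness, SimulationSpec
>>> from icolike.simulate import generate_sine_base, inject_outlier
>>> spec = SimulationSpec().with_outlier("inconsistent", x=3.0, delta_y=1.5)
>>> data = inject_outlier(generate_sine_base(), spec)
>>> res = ICOLikeness.from_dataset(data, backend="ols", top_k=5).fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .backends import BackendConfig
from .core import (
    CandidateList,
    ClassificationRule,
    CVCache,
    ICORecord,
    classify_records,
    ico_likeness,
    rank_by_abs_error,
)
from .cv import (
    CVMetrics,
    CVSettings,
    FoldPlan,
    OuterPredictions,
    compute_metrics,
    make_fold_plan,
    run_outer_cv,
)
from .dataset import Dataset
from .exceptions import InputError

__all__ = ["ICOLikeness", "ICOResults"]

REPORT_COLUMNS = ["candidate_id", "abs_error", "mae_wos", "mae_woos",
                  "ico_likeness", "label"]


class ICOLikeness:
    """Consistent-vs-inconsistent outlier diagnosis for a regression dataset.

    Parameters
    ----------
    X : array-like, shape (n, p)
        Feature matrix.
    y : array-like, shape (n,)
        Target values.
    ids : sequence of str, optional
        Sample identifiers; defaults to ``"1".."n"``.
    backend : str or BackendConfig
        Regression backend: ``"gpr"`` (default) or ``"ols"``, or a full
        :class:`~icolike.backends.BackendConfig`.
    outer_k : int or "loo"
        Outer fold count of the double cross-validation.
    seed : int
        Seed for fold shuffling and backend hyperparameter restarts.
    top_k : int or "all"
        How many of the largest-error samples to score.  Scoring all
        samples gives the most faithful reference level for the robust
        classification rule; a small ``top_k`` trades that for speed.
    rule : ClassificationRule, optional
        CO/ICO decision rule; defaults to the robust median + 3*MAD rule.
    """

    def __init__(self, X, y, ids=None, *, backend="gpr",
                 outer_k: int | str = "loo", seed: int = 0,
                 top_k: int | str = "all",
                 rule: ClassificationRule | None = None,
                 feature_names=None) -> None:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if ids is None:
            ids = tuple(str(i + 1) for i in range(X.shape[0]))
        self.dataset = Dataset(ids=tuple(ids), X=X, y=np.asarray(y, dtype=float),
                               feature_names=tuple(feature_names or ()))
        if isinstance(backend, BackendConfig):
            self.backend = backend
        else:
            self.backend = BackendConfig(backend=str(backend), seed=seed)
        self.cv = CVSettings(outer_k=outer_k, seed=seed)
        self.top_k = top_k
        self.rule = rule or ClassificationRule()
        self.seed = int(seed)

    @classmethod
    def from_dataset(cls, dataset: Dataset, **kwargs) -> "ICOLikeness":
        return cls(dataset.X, dataset.y, ids=dataset.ids,
                   feature_names=dataset.feature_names, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str = "y",
                       features=None, ids: str | None = None,
                       **kwargs) -> "ICOLikeness":
        """Build from a DataFrame: a target column, feature columns, and an
        optional id column (all remaining numeric columns are features when
        ``features`` is omitted)."""
        if target not in df.columns:
            raise InputError(f"target column {target!r} not in frame")
        id_values = None
        drop = [target]
        if ids is not None:
            if ids not in df.columns:
                raise InputError(f"id column {ids!r} not in frame")
            id_values = [str(v) for v in df[ids]]
            drop.append(ids)
        if features is None:
            features = [c for c in df.columns if c not in drop]
        else:
            features = list(features)
            if target in features:
                raise InputError("target column listed among features")
            missing = [c for c in features if c not in df.columns]
            if missing:
                raise InputError(f"feature columns not in frame: {missing}")
        if not features:
            raise InputError("no feature columns")
        return cls(df[features].to_numpy(dtype=float),
                   df[target].to_numpy(dtype=float),
                   ids=id_values, feature_names=features, **kwargs)

    def fit(self, *, cache: CVCache | None = None) -> "ICOResults":
        """Run the full diagnostic: outer CV, candidate ranking, per-candidate
        ICO-likeness, and CO/ICO classification."""
        ds = self.dataset
        k = self.cv.resolve_k(ds.n_samples)
        plan = make_fold_plan(ds.ids, k, self.cv.seed)
        full_preds = run_outer_cv(ds, plan, self.backend)
        metrics = compute_metrics(full_preds, ds)
        candidates = rank_by_abs_error(full_preds, self.top_k)
        cache = cache if cache is not None else CVCache()
        records: list[ICORecord] = []
        for cid in candidates.ids:
            rec = ico_likeness(ds, cid, self.backend, self.cv, plan=plan,
                               full_predictions=full_preds if plan.is_loo else None,
                               cache=cache)
            if np.isnan(rec.abs_error):
                rec = replace(rec, abs_error=candidates.abs_error_of(cid))
            records.append(rec)
        labeled = classify_records(records, self.rule)
        return ICOResults(model=self, fold_plan=plan, predictions=full_preds,
                          metrics=metrics, candidates=candidates,
                          records=tuple(labeled))


@dataclass(frozen=True)
class ICOResults:
    """Fitted diagnostic: metrics, scored candidates, labels, reporting."""

    model: ICOLikeness
    fold_plan: FoldPlan
    predictions: OuterPredictions
    metrics: CVMetrics
    candidates: CandidateList
    records: tuple[ICORecord, ...]

    def record_for(self, sample_id: str) -> ICORecord:
        for r in self.records:
            if r.candidate_id == str(sample_id):
                return r
        raise InputError(f"{sample_id!r} was not scored")

    def to_frame(self) -> pd.DataFrame:
        """Candidate report: one row per scored candidate."""
        return pd.DataFrame(
            [{c: getattr(r, c) for c in REPORT_COLUMNS} for r in self.records],
            columns=REPORT_COLUMNS,
        )

    @property
    def ico_ids(self) -> tuple[str, ...]:
        return tuple(r.candidate_id for r in self.records if r.label == "ICO")

    def plot_frame(self) -> pd.DataFrame:
        """Scatter data (absolute DCV error vs ICO-likeness) for every
        scored sample."""
        return self.to_frame()[["candidate_id", "abs_error",
                                "ico_likeness", "label"]]

    def plot(self, ax=None):
        """Absolute outer prediction error vs ICO-likeness, ICO points marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        df = self.plot_frame()
        co = df[df["label"] != "ICO"]
        ico = df[df["label"] == "ICO"]
        ax.scatter(co["abs_error"], co["ico_likeness"], c="tab:blue",
                   label="CO / normal", s=25)
        if len(ico):
            ax.scatter(ico["abs_error"], ico["ico_likeness"], c="tab:red",
                       marker="x", s=60, label="ICO")
            for _, row in ico.iterrows():
                ax.annotate(row["candidate_id"],
                            (row["abs_error"], row["ico_likeness"]),
                            textcoords="offset points", xytext=(4, 4))
        ax.set_xlabel("absolute prediction error of y in DCV")
        ax.set_ylabel("ICO-likeness")
        ax.legend()
        return ax

    def summary(self) -> str:
        m = self.model
        lines = [
            "ICO-likeness outlier diagnosis",
            "=" * 64,
            f"n samples:        {m.dataset.n_samples}",
            f"n features:       {m.dataset.n_features}",
            f"backend:          {m.backend.backend} "
            f"(restarts={m.backend.n_restarts}, seed={m.backend.seed})",
            f"outer folds:      "
            f"{'leave-one-out' if self.fold_plan.is_loo else self.fold_plan.k}",
            f"fold plan digest: {self.fold_plan.digest()}",
            f"DCV MAE:          {self.metrics.mae:.6g}",
            f"DCV R2:           {self.metrics.r2:.6g}",
            f"candidates scored: {len(self.records)}"
            f"  (ICO: {len(self.ico_ids)})",
            "-" * 64,
        ]
        df = self.to_frame()
        with pd.option_context("display.float_format", "{:11.6g}".format):
            lines.append(df.to_string(index=False))
        return "\n".join(lines)
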