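"""The tabular sample container used throughout the package.

A :class:`Dataset` is an immutable bundle of unique sample identifiers, a
finite feature matrix ``X`` (n samples x p features) and a finite target
vector ``y``.  It is deliberately small: anything richer (missing-value
handling, column selection) happens at read time in :mod:`icolike.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = ["Dataset"]


@dataclass(frozen=True)
class Dataset:
    """Sample identifiers, feature matrix and target vector.

    Parameters
    ----------
    ids : tuple of str
        Unique, ordered sample identifiers.
    X : ndarray, shape (n, p)
        Finite feature matrix.
    y : ndarray, shape (n,)
        Finite target values.
    feature_names : tuple of str, optional
        Column labels for ``X``; defaults to ``x0..x{p-1}``.
    """

    ids: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if X.ndim != 2:
            raise InputError(f"X must be 2-dimensional, got ndim={X.ndim}")
        if y.ndim != 1:
            raise InputError(f"y must be 1-dimensional, got ndim={y.ndim}")
        ids = tuple(str(i) for i in self.ids)
        if len(ids) != X.shape[0] or len(ids) != y.shape[0]:
            raise InputError(
                f"length mismatch: {len(ids)} ids, {X.shape[0]} feature rows, "
                f"{y.shape[0]} targets"
            )
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sample ids: {dupes}")
        if not np.all(np.isfinite(X)):
            raise InputError("X contains non-finite values")
        if not np.all(np.isfinite(y)):
            raise InputError("y contains non-finite values")
        names = tuple(self.feature_names) or tuple(
            f"x{j}" for j in range(X.shape[1])
        )
        if len(names) != X.shape[1]:
            raise InputError(
                f"{len(names)} feature names for {X.shape[1]} feature columns"
            )
        X.setflags(write=False)
        y.setflags(write=False)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_names", names)

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return int(self.X.shape[1])

    def index_of(self, sample_id: str) -> int:
        try:
            return self.ids.index(str(sample_id))
        except ValueError:
            raise InputError(f"unknown sample id: {sample_id!r}") from None

    def y_of(self, sample_id: str) -> float:
        return float(self.y[self.index_of(sample_id)])

    def subset(self, keep_ids) -> "Dataset":
        """Rows for ``keep_ids``, preserving this dataset's row order."""
        keep = {str(i) for i in keep_ids}
        unknown = keep - set(self.ids)
        if unknown:
            raise InputError(f"unknown sample ids: {sorted(unknown)}")
        mask = [i in keep for i in self.ids]
        return Dataset(
            ids=tuple(i for i, m in zip(self.ids, mask) if m),
            X=self.X[mask],
            y=self.y[mask],
            feature_names=self.feature_names,
        )

    def drop(self, sample_id: str) -> "Dataset":
        """Dataset without one sample."""
        idx = self.index_of(sample_id)
        mask = np.ones(self.n_samples, dtype=bool)
        mask[idx] = False
        return Dataset(
            ids=tuple(i for j, i in enumerate(self.ids) if j != idx),
            X=self.X[mask],
            y=self.y[mask],
            feature_names=self.feature_names,
        )

    def to_frame(self, id_column: str = "sample_id",
                 target_column: str = "y") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, id_column, list(self.ids))
        df[target_column] = self.y
        return df

    def content_key(self) -> bytes:
        """Stable digest of ids + values, for cross-validation caching."""
        import hashlib

        h = hashlib.sha256()
        h.update("\x1f".join(self.ids).encode())
        h.update(np.ascontiguousarray(self.X).tobytes())
        h.update(np.ascontiguousarray(self.y).tobytes())
        return h.digest()
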