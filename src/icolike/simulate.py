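"""Synthetic benchmarks: the sine-curve system with injectable outliers.

The reference benchmark takes y = sin(x) on the grid x = z/6 for integer
z = 0..44 (45 noiseless samples spanning about 1.2 periods), then appends a
single 46th sample in one of two modes:

* ``inconsistent`` — an interior x whose y is shifted off the curve by a
  non-zero delta: no function of x consistent with the other samples can
  produce it (an ICO by construction);
* ``consistent`` — a point exactly on the curve but at an x beyond the
  sampled range: extreme, yet perfectly consistent (a CO by construction).

A generic noisy generator over named test functions rounds out the module
so every other component can be exercised without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import Dataset
from .exceptions import InputError

__all__ = [
    "SimulationSpec",
    "generate_sine_base",
    "inject_outlier",
    "generate_generic",
    "GENERIC_FUNCTIONS",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the sine benchmark and its outlier injection.

    The base grid is ``x = z * x_scale`` for integer ``z`` in
    ``z_start..z_end`` inclusive; targets are ``sin(x)`` plus optional
    Gaussian noise (the reference benchmark is noiseless).  Outlier
    placement defaults: the inconsistent mode puts the extra point at an
    interior x with its y shifted by ``outlier_delta_y``; the consistent
    mode puts it on the curve beyond the sampled range.
    """

    z_start: int = 0
    z_end: int = 44
    x_scale: float = 1.0 / 6.0
    outlier_mode: str = "none"  # {"none", "inconsistent", "consistent"}
    outlier_x: float = float("nan")
    outlier_delta_y: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z_end < self.z_start:
            raise InputError(f"z_end={self.z_end} < z_start={self.z_start}")
        if self.x_scale <= 0:
            raise InputError(f"x_scale must be positive, got {self.x_scale}")
        if self.outlier_mode not in ("none", "inconsistent", "consistent"):
            raise InputError(f"unknown outlier_mode {self.outlier_mode!r}")
        if self.noise_sd < 0:
            raise InputError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def n_base(self) -> int:
        return self.z_end - self.z_start + 1

    @property
    def x_range(self) -> tuple[float, float]:
        return (self.z_start * self.x_scale, self.z_end * self.x_scale)

    def with_outlier(self, mode: str, x: float,
                     delta_y: float = 0.0) -> "SimulationSpec":
        return replace(self, outlier_mode=mode, outlier_x=float(x),
                       outlier_delta_y=float(delta_y))


def generate_sine_base(spec: SimulationSpec | None = None) -> Dataset:
    """Generate the sine-curve base samples (45 for the default spec)."""
    spec = spec or SimulationSpec()
    if spec.outlier_mode != "none":
        raise InputError("generate_sine_base requires outlier_mode='none'; "
                         "use inject_outlier for the extra sample")
    z = np.arange(spec.z_start, spec.z_end + 1)
    # when x_scale is 1/m for integer m, divide so the grid z/m is exact
    denom = 1.0 / spec.x_scale
    if denom == round(denom):
        x = z / denom
    else:
        x = z * spec.x_scale
    y = np.sin(x)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    ids = tuple(str(i + 1) for i in range(len(z)))
    return Dataset(ids=ids, X=x.reshape(-1, 1), y=y, feature_names=("x",))


def inject_outlier(dataset: Dataset, spec: SimulationSpec) -> Dataset:
    """Append the 46th-style sample according to the spec's outlier mode.

    Base rows are preserved bit-for-bit; the new sample's id is the next
    integer after the base (``"46"`` for the default benchmark).
    """
    if spec.outlier_mode == "none":
        raise InputError("outlier_mode must be 'inconsistent' or 'consistent'")
    x = float(spec.outlier_x)
    if not np.isfinite(x):
        raise InputError("outlier_x must be set and finite")
    lo, hi = spec.x_range
    if spec.outlier_mode == "inconsistent":
        if not lo <= x <= hi:
            raise InputError(
                f"inconsistent outlier_x={x} must lie inside [{lo:g}, {hi:g}]"
            )
        if spec.outlier_delta_y == 0.0:
            raise InputError("inconsistent mode requires a non-zero delta_y")
        y = float(np.sin(x) + spec.outlier_delta_y)
    else:  # consistent: on-curve, extrapolated
        if lo <= x <= hi:
            raise InputError(
                f"consistent outlier_x={x} must lie outside [{lo:g}, {hi:g}]"
            )
        y = float(np.sin(x))
    new_id = str(dataset.n_samples + 1)
    if new_id in dataset.ids:
        new_id = max(dataset.ids, key=len) + "_outlier"
    return Dataset(
        ids=dataset.ids + (new_id,),
        X=np.vstack([dataset.X, [[x]]]),
        y=np.append(dataset.y, y),
        feature_names=dataset.feature_names,
    )


GENERIC_FUNCTIONS = {
    "linear": lambda x: 2.0 * x + 1.0,
    "sine": np.sin,
    "quadratic": lambda x: x**2,
}

#: x interval used by :func:`generate_generic`.
_GENERIC_INTERVAL = (0.0, 10.0)


def generate_generic(n: int, fn: str = "linear", noise_sd: float = 0.0,
                     seed: int = 0) -> Dataset:
    """Equally spaced x on [0, 10], y = fn(x) + Gaussian noise."""
    n = int(n)
    if n < 4:
        raise InputError(f"n must be >= 4, got {n}")
    if fn not in GENERIC_FUNCTIONS:
        raise InputError(
            f"unknown function {fn!r}; choose from {sorted(GENERIC_FUNCTIONS)}"
        )
    if noise_sd < 0:
        raise InputError(f"noise_sd must be >= 0, got {noise_sd}")
    x = np.linspace(*_GENERIC_INTERVAL, n)
    y = GENERIC_FUNCTIONS[fn](x)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=n)
    ids = tuple(str(i + 1) for i in range(n))
    return Dataset(ids=ids, X=x.reshape(-1, 1), y=y, feature_names=("x",))
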