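"""Core in-memory containers shared across estimation modules.

Conventions
-----------
Coefficient matrices are indexed ``[source, target]`` throughout: entry
``K[i, j]`` is the lagged influence of region ``i`` on region ``j``, so the
autoregression reads ``y_j(t) = sum_m sum_i K[i, j, m] * y_i(t - m) + n_j(t)``.
Causality tensors inherit the same orientation: ``DGC[i, j, t]`` quantifies the
directed influence i -> j at time t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class SamplingFailureError(RuntimeError):
    """Rejection sampling exceeded its retry cap."""


class SingularFitError(np.linalg.LinAlgError):
    """The regressor matrix is rank deficient."""


def default_region_names(n: int) -> list[str]:
    return [f"R{i + 1}" for i in range(n)]


@dataclass
class TimeSeriesMatrix:
    """T x R multivariate series (rows = time points, columns = regions)."""

    values: np.ndarray
    region_names: list[str] = field(default_factory=list)
    sampling_interval: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("time series must be a 2-D (time x regions) array")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("time series contains non-finite values")
        if not self.region_names:
            self.region_names = default_region_names(self.values.shape[1])
        if len(self.region_names) != self.values.shape[1]:
            raise InvalidArgumentError("region_names length does not match column count")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class MVARModel:
    """Static multivariate autoregressive fit.

    ``lag_coeffs`` has shape (R, R, p); slice ``[..., m]`` is the coefficient
    matrix at lag m+1 in source->target orientation.
    """

    order: int
    lag_coeffs: np.ndarray
    intercept: np.ndarray
    residual_cov: np.ndarray
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lag_coeffs = np.asarray(self.lag_coeffs, dtype=float)
        if self.order < 1:
            raise InvalidArgumentError("model order must be >= 1")
        if self.lag_coeffs.shape[2] != self.order:
            raise InvalidArgumentError("lag_coeffs third dimension must equal order")


@dataclass
class DynamicCoeffs:
    """Time-varying MVAR coefficients K(m, t), shape (R, R, p, T)."""

    values: np.ndarray
    forgetting: float
    init_coeffs: np.ndarray | None = None
    residuals: np.ndarray | None = None  # one-step-ahead (a priori) errors, T x R

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise InvalidArgumentError("dynamic coefficients must have shape (R, R, p, T)")
        if not (0.0 <= self.forgetting < 1.0):
            raise InvalidArgumentError("forgetting must lie in [0, 1)")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("dynamic coefficients contain non-finite values")

    @property
    def order(self) -> int:
        return self.values.shape[2]

    @property
    def n_time(self) -> int:
        return self.values.shape[3]


@dataclass
class DGCTensor:
    """Nonnegative dynamic causality values, shape (R, R, T)."""

    values: np.ndarray
    burn_in_removed: bool = False
    burn_in_length: int = 0
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise InvalidArgumentError("DGC tensor must have shape (R, R, T)")
        if np.any(self.values < 0):
            raise InvalidArgumentError("DGC values must be nonnegative")
        if not self.region_names:
            self.region_names = default_region_names(self.values.shape[0])

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[2]
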