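"""Static and time-varying MVAR estimation and Granger causality.

The static model is ``Y(t) = B + sum_m K(m) Y(t-m) + N(t)`` fit by ordinary
least squares; static Granger causality from region i to region j is the sum
over lags of the squared cross-coefficients, ``G_ij = sum_m k_ij(m)^2``.

The time-varying model lets the coefficients drift, ``K(m) -> K(m, t)``, and is
estimated with recursive least squares under exponential forgetting: sample
t-s is down-weighted by ``(1 - F)^s``, so the forgetting factor F trades
tracking speed against estimator variance (F = 0 is the no-forgetting limit
and reproduces a growing-window OLS).  Dynamic Granger causality (DGC) is the
per-time analogue ``DGC_ij(t) = sum_m k_ij(m, t)^2``.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import (
    DGCTensor,
    DynamicCoeffs,
    InvalidArgumentError,
    MVARModel,
    SingularFitError,
    TimeSeriesMatrix,
)

#: default initial inverse-correlation scale (P0 = DELTA * I)
DELTA = 1000.0
#: default recursive-estimator burn-in, in samples
DEFAULT_BURN_IN = 50
#: default search grid for the forgetting factor
DEFAULT_FORGETTING_GRID = (0.01, 0.02, 0.05, 0.10, 0.15, 0.20)


def _design(values: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack lagged regressors: X[t] = [y(t-1), ..., y(t-p)], target Y[t] = y(t)."""
    t_total, n_regions = values.shape
    rows = t_total - order
    x = np.empty((rows, n_regions * order))
    for m in range(1, order + 1):
        x[:, (m - 1) * n_regions : m * n_regions] = values[order - m : t_total - m]
    return x, values[order:]


def fit_static_mvar(series: TimeSeriesMatrix, order: int) -> MVARModel:
    """Ordinary least-squares MVAR fit (all targets solved jointly).

    Data are mean-centered before fitting; the intercept is reconstructed from
    the means and is ~0 for already-centered input.
    """
    if order < 1:
        raise InvalidArgumentError("order must be >= 1")
    values = series.values
    t_total, n_regions = values.shape
    if t_total <= n_regions * order + 1:
        raise InvalidArgumentError(
            f"need T > R*order + 1 samples (T={t_total}, R={n_regions}, order={order})"
        )
    means = values.mean(axis=0)
    centered = values - means
    x, y = _design(centered, order)
    coeffs, _, rank, sing = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        tol = max(x.shape) * np.finfo(float).eps * sing[0]
        bad = np.where(sing < tol)[0]
        raise SingularFitError(
            f"rank-deficient regressor matrix (rank {rank} < {x.shape[1]}); "
            f"near-null singular directions at indices {bad.tolist()}"
        )
    residuals = y - x @ coeffs
    residual_cov = residuals.T @ residuals / residuals.shape[0]
    lag_coeffs = np.transpose(coeffs.reshape(order, n_regions, n_regions), (1, 2, 0))
    # y(t) = mu + sum_m K(m)^T (y(t-m) - mu) => intercept in the uncentered model
    intercept = means - sum(lag_coeffs[:, :, m].T @ means for m in range(order))
    return MVARModel(
        order=order,
        lag_coeffs=lag_coeffs,
        intercept=intercept,
        residual_cov=residual_cov,
        region_names=list(series.region_names),
    )


def static_gc(model: MVARModel) -> np.ndarray:
    """Static Granger causality matrix: G[i, j] = sum_m K[i, j, m]^2."""
    return np.sum(model.lag_coeffs**2, axis=2)


def select_order_bic(series: TimeSeriesMatrix, max_order: int) -> int:
    """Model order minimizing BIC; ties break toward the smaller order."""
    if max_order < 1:
        raise InvalidArgumentError("max_order must be >= 1")
    n_regions = series.n_regions
    bics = []
    for order in range(1, max_order + 1):
        model = fit_static_mvar(series, order)
        t_eff = series.n_time - order
        sign, logdet = np.linalg.slogdet(model.residual_cov)
        if sign <= 0:
            bics.append(np.inf)
            continue
        loglik = -0.5 * t_eff * (n_regions * np.log(2 * np.pi) + logdet + n_regions)
        bics.append(-2.0 * loglik + (n_regions**2 * order) * np.log(t_eff))
    return int(np.argmin(bics)) + 1


def _rls_pass(
    values: np.ndarray,
    order: int,
    lam: float,
    w0: np.ndarray,
    p0: np.ndarray,
    delta: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One recursive-least-squares sweep.

    Returns the per-time stacked coefficients (T, d, R), a priori residuals
    (T, R), and the final (W, P) filter state.
    """
    t_total, n_regions = values.shape
    d = n_regions * order
    w = w0.copy()
    p = p0.copy()
    track = np.empty((t_total, d, n_regions))
    resid = np.full((t_total, n_regions), np.nan)
    track[:order] = w
    for t in range(order, t_total):
        x = values[t - order : t][::-1].ravel()  # [y(t-1), ..., y(t-p)]
        px = p @ x
        denom = lam + x @ px
        if not np.isfinite(denom) or denom <= 0.0:
            warnings.warn(
                "regularized restart: recursive gain update became singular",
                RuntimeWarning,
                stacklevel=3,
            )
            p = delta * np.eye(d)
            px = p @ x
            denom = lam + x @ px
        gain = px / denom
        err = values[t] - w.T @ x
        resid[t] = err
        w = w + np.outer(gain, err)
        p = (p - np.outer(gain, px)) / lam
        p = (p + p.T) / 2.0  # keep P symmetric against round-off drift
        track[t] = w
    return track, resid, w, p


def _stack_init(init_coeffs: np.ndarray, n_regions: int, order: int) -> np.ndarray:
    init = np.asarray(init_coeffs, dtype=float)
    if init.shape != (n_regions, n_regions, order):
        raise InvalidArgumentError(
            f"init_coeffs must have shape {(n_regions, n_regions, order)}, got {init.shape}"
        )
    # row block m holds lag m+1, matching the regressor stacking in _design/_rls_pass
    return np.concatenate([init[:, :, m] for m in range(order)], axis=0)


def fit_dynamic_mvar(
    series: TimeSeriesMatrix,
    order: int,
    forgetting: float,
    init_coeffs: np.ndarray | None = None,
    delta: float = DELTA,
) -> DynamicCoeffs:
    """Recursive least squares with exponential forgetting.

    ``forgetting`` is F in (0, 1): the weight on a sample s steps in the past
    decays as (1-F)^s. F = 0 is accepted as the no-forgetting limit, in which
    the final-time estimate coincides with a growing-window OLS fit. The data
    are mean-centered before filtering (the intercept is absorbed).
    """
    if not (0.0 <= forgetting < 1.0):
        raise InvalidArgumentError("forgetting must lie in [0, 1)")
    if order < 1:
        raise InvalidArgumentError("order must be >= 1")
    values = series.values - series.values.mean(axis=0)
    t_total, n_regions = values.shape
    d = n_regions * order
    if t_total <= order:
        raise InvalidArgumentError("series shorter than the model order")
    w0 = (
        np.zeros((d, n_regions))
        if init_coeffs is None
        else _stack_init(init_coeffs, n_regions, order)
    )
    track, resid, _, _ = _rls_pass(
        values, order, 1.0 - forgetting, w0, delta * np.eye(d), delta
    )
    # (T, d, R) -> (R, R, p, T) with K[i, j, m, t]
    per_lag = track.reshape(t_total, order, n_regions, n_regions)
    coeff_tensor = np.transpose(per_lag, (2, 3, 1, 0))
    return DynamicCoeffs(
        values=coeff_tensor,
        forgetting=forgetting,
        init_coeffs=None if init_coeffs is None else np.asarray(init_coeffs, float),
        residuals=resid,
    )


def dgc(coeffs: DynamicCoeffs, region_names: list[str] | None = None) -> DGCTensor:
    """Dynamic Granger causality: elementwise sum over lags of squared coefficients."""
    values = np.sum(coeffs.values**2, axis=2)
    return DGCTensor(values=values, region_names=region_names or [])


def forgetting_objective(
    series: TimeSeriesMatrix,
    order: int,
    forgetting: float,
    burn_in: int = DEFAULT_BURN_IN,
) -> float:
    """Variance over time of the squared one-step-ahead residual energy.

    The residual energy at time t pools the squared prediction errors over all
    regions; the variance is taken over post-burn-in times.
    """
    fit = fit_dynamic_mvar(series, order, forgetting)
    energy = np.nansum(fit.residuals**2, axis=1)[max(burn_in, order) :]
    return float(np.var(energy))


def optimize_forgetting(
    series: TimeSeriesMatrix,
    order: int,
    grid: tuple[float, ...] = DEFAULT_FORGETTING_GRID,
    burn_in: int = DEFAULT_BURN_IN,
) -> float:
    """Grid search for the forgetting factor minimizing the residual-energy variance."""
    if len(grid) == 0:
        raise InvalidArgumentError("forgetting grid must be nonempty")
    objectives = [forgetting_objective(series, order, f, burn_in) for f in grid]
    return float(grid[int(np.argmin(objectives))])


def group_initialize(
    runs: list[TimeSeriesMatrix],
    order: int,
    forgetting: float,
    delta: float = DELTA,
) -> np.ndarray:
    """Sequentially filter all runs, chaining the filter state between them.

    Run 1 starts from zero coefficients; each later run starts from the state
    the previous run ended in. The returned (R, R, p) coefficient array is the
    group-level initial condition for per-run re-estimation. The result depends
    on run order (documented behaviour of the sequential pass).
    """
    if not runs:
        raise InvalidArgumentError("need at least one run")
    n_regions = runs[0].n_regions
    if any(r.n_regions != n_regions for r in runs):
        raise InvalidArgumentError("all runs must share the same number of regions")
    d = n_regions * order
    w = np.zeros((d, n_regions))
    p = delta * np.eye(d)
    lam = 1.0 - forgetting
    for run in runs:
        centered = run.values - run.values.mean(axis=0)
        _, _, w, p = _rls_pass(centered, order, lam, w, p, delta)
    per_lag = w.reshape(order, n_regions, n_regions)
    return np.transpose(per_lag, (1, 2, 0))


def burn_in_trim(tensor: DGCTensor, n_discard: int = DEFAULT_BURN_IN) -> DGCTensor:
    """Discard the first ``n_discard`` time slices (recursive-filter convergence)."""
    if n_discard < 0:
        raise InvalidArgumentError("n_discard must be >= 0")
    if n_discard == 0:
        return DGCTensor(
            values=tensor.values.copy(),
            burn_in_removed=tensor.burn_in_removed,
            burn_in_length=tensor.burn_in_length,
            region_names=list(tensor.region_names),
        )
    if n_discard >= tensor.n_time:
        raise InvalidArgumentError(
            f"n_discard={n_discard} must be smaller than T={tensor.n_time}"
        )
    return DGCTensor(
        values=tensor.values[:, :, n_discard:].copy(),
        burn_in_removed=True,
        burn_in_length=tensor.burn_in_length + n_discard,
        region_names=list(tensor.region_names),
    )
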