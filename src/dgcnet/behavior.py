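"""Behavioral variance partitioning between dynamic and static connectivity.

For each (behavioral test i, connection j) cell a two-regressor linear model

    B_i = alpha_ij * DEC_j + beta_ij * SEC_j + eps

is fit, where DEC is the variance over time of the dynamic causality of
connection j (how much the connection fluctuates) and SEC is the absolute
static causality (how strong it is on average).  Regressors (and the behavior
vector) are mean-centered per cell; there is no intercept.  Coefficients are
tested with a z-test against the normal reference, Bonferroni-corrected across
behavioral tests.  The explained-variance fractions compare the mean of
(alpha*DEC)^2 with the mean of (beta*SEC)^2 over all cells and observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import DGCTensor, InvalidArgumentError

#: |correlation| between DEC and SEC above which a cell is flagged collinear
COLLINEARITY_LIMIT = 0.999


@dataclass
class ECMetrics:
    """Per-observation (run) connectivity metrics, one column per connection."""

    dec: np.ndarray  # (n_obs, n_connections) variance over time of DGC
    sec: np.ndarray  # (n_obs, n_connections) |static GC|
    connection_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dec = np.atleast_2d(np.asarray(self.dec, dtype=float))
        self.sec = np.atleast_2d(np.asarray(self.sec, dtype=float))
        if self.dec.shape != self.sec.shape:
            raise InvalidArgumentError("dec and sec must have identical shapes")
        if np.any(self.dec < 0) or np.any(self.sec < 0):
            raise InvalidArgumentError("EC metrics must be nonnegative")
        if not self.connection_names:
            self.connection_names = [f"c{j}" for j in range(self.dec.shape[1])]


@dataclass
class BehaviorGLMResult:
    alpha: np.ndarray  # (n_tests, n_connections)
    beta: np.ndarray
    z_alpha: np.ndarray
    z_beta: np.ndarray
    p_alpha: np.ndarray
    p_beta: np.ndarray
    bonferroni_threshold: float
    skipped_collinear: np.ndarray  # boolean mask of skipped cells
    standardized: bool = False
    dec_centered: np.ndarray | None = None  # regressors as used in the fit
    sec_centered: np.ndarray | None = None


def connection_names_from_regions(region_names: list[str]) -> list[str]:
    """Off-diagonal connection labels 'SRC->DST' in row-major order."""
    return [
        f"{src}->{dst}" for src in region_names for dst in region_names if src != dst
    ]


def compute_ec_metrics(tensor: DGCTensor, static_gc_matrix: np.ndarray) -> ECMetrics:
    """Single-run metrics: time-variance of DGC and |static GC| per connection."""
    if not tensor.burn_in_removed:
        warnings.warn(
            "DGC tensor has not been burn-in trimmed; metrics include transients",
            RuntimeWarning,
            stacklevel=2,
        )
    n = tensor.n_regions
    mask = ~np.eye(n, dtype=bool)
    dec = np.var(tensor.values, axis=2)[mask]
    sec = np.abs(np.asarray(static_gc_matrix, dtype=float))[mask]
    return ECMetrics(
        dec=dec[None, :],
        sec=sec[None, :],
        connection_names=connection_names_from_regions(tensor.region_names),
    )


def stack_runs(metrics: list[ECMetrics]) -> ECMetrics:
    """Stack per-run metrics into the observations-by-connections layout."""
    if not metrics:
        raise InvalidArgumentError("need at least one run")
    return ECMetrics(
        dec=np.vstack([m.dec for m in metrics]),
        sec=np.vstack([m.sec for m in metrics]),
        connection_names=list(metrics[0].connection_names),
    )


def bonferroni_threshold(family_alpha: float = 0.05, n_tests: int = 70) -> float:
    """Per-test significance level under Bonferroni correction."""
    return family_alpha / n_tests


def fit_behavior_glm(
    behavior: np.ndarray,
    metrics: ECMetrics,
    duplicate_runs: bool = True,
    family_alpha: float = 0.05,
    standardize: bool = False,
) -> BehaviorGLMResult:
    """Fit the per-(test, connection) two-regressor model.

    ``behavior`` is subjects x tests; with ``duplicate_runs`` each subject's
    score is repeated for every run (the metrics rows must then come in
    subject-major run order, n_obs = n_subjects * runs_per_subject).
    """
    b = np.atleast_2d(np.asarray(behavior, dtype=float))
    n_obs = metrics.dec.shape[0]
    if duplicate_runs:
        if n_obs % b.shape[0] != 0:
            raise InvalidArgumentError(
                "observation count is not a multiple of the subject count"
            )
        b = np.repeat(b, n_obs // b.shape[0], axis=0)
    if b.shape[0] != n_obs:
        raise InvalidArgumentError("behavior rows must align with metric observations")
    if n_obs < 3:
        raise InvalidArgumentError("need at least 3 observations per fit")
    n_tests = b.shape[1]
    n_conn = metrics.dec.shape[1]

    d = metrics.dec - metrics.dec.mean(axis=0)
    s = metrics.sec - metrics.sec.mean(axis=0)
    if standardize:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(d.std(axis=0) > 0, d / d.std(axis=0), d)
            s = np.where(s.std(axis=0) > 0, s / s.std(axis=0), s)
    bc = b - b.mean(axis=0)

    # per-connection Gram entries of the 2x2 normal equations
    dd = np.sum(d * d, axis=0)
    ss = np.sum(s * s, axis=0)
    ds = np.sum(d * s, axis=0)
    det = dd * ss - ds**2
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = ds / np.sqrt(dd * ss)
    collinear = (~np.isfinite(corr)) | (np.abs(corr) > COLLINEARITY_LIMIT) | (det <= 0)
    if np.any(collinear):
        warnings.warn(
            f"{int(collinear.sum())} connection(s) skipped: DEC/SEC collinear",
            RuntimeWarning,
            stacklevel=2,
        )

    db = bc.T @ d  # (n_tests, n_conn)
    sb = bc.T @ s
    shape = (n_tests, n_conn)
    alpha = np.full(shape, np.nan)
    beta = np.full(shape, np.nan)
    var_alpha = np.full(shape, np.nan)
    var_beta = np.full(shape, np.nan)
    ok = ~collinear
    alpha[:, ok] = (ss[ok] * db[:, ok] - ds[ok] * sb[:, ok]) / det[ok]
    beta[:, ok] = (dd[ok] * sb[:, ok] - ds[ok] * db[:, ok]) / det[ok]

    dof = n_obs - 2
    # residual sum of squares per cell, from the quadratic form
    bb = np.sum(bc * bc, axis=0)  # (n_tests,)
    rss = (
        bb[:, None]
        - 2 * alpha * db
        - 2 * beta * sb
        + alpha**2 * dd[None]
        + beta**2 * ss[None]
        + 2 * alpha * beta * ds[None]
    )
    rss = np.clip(rss, 0.0, None)
    sigma2 = rss / dof
    var_alpha[:, ok] = sigma2[:, ok] * ss[ok] / det[ok]
    var_beta[:, ok] = sigma2[:, ok] * dd[ok] / det[ok]
    with np.errstate(invalid="ignore", divide="ignore"):
        z_alpha = alpha / np.sqrt(var_alpha)
        z_beta = beta / np.sqrt(var_beta)
    p_alpha = 2.0 * stats.norm.sf(np.abs(z_alpha))
    p_beta = 2.0 * stats.norm.sf(np.abs(z_beta))
    collinear_mask = np.broadcast_to(collinear, shape).copy()
    return BehaviorGLMResult(
        alpha=alpha,
        beta=beta,
        z_alpha=z_alpha,
        z_beta=z_beta,
        p_alpha=p_alpha,
        p_beta=p_beta,
        bonferroni_threshold=bonferroni_threshold(family_alpha, n_tests),
        skipped_collinear=collinear_mask,
        standardized=standardize,
        dec_centered=d,
        sec_centered=s,
    )


def variance_fractions(
    result: BehaviorGLMResult, metrics: ECMetrics | None = None
) -> tuple[float, float, float]:
    """Mean explained variances and the DEC fraction.

    var_dec is the grand mean over cells and observations of (alpha*DEC)^2
    using the regressor values as fit (centered/standardized); var_sec is the
    analogue for SEC; frac_dec = var_dec / (var_dec + var_sec).  Cells skipped
    for collinearity are excluded from both numerator and denominator.
    """
    d = result.dec_centered
    s = result.sec_centered
    if d is None or s is None:
        raise InvalidArgumentError("result does not carry its fitted regressors")
    ok = ~result.skipped_collinear
    if not np.any(ok):
        raise InvalidArgumentError("no non-collinear cells to aggregate")
    # (n_tests, n_conn, n_obs) contributions, averaged over everything kept
    contrib_d = (result.alpha[:, :, None] * d.T[None]) ** 2
    contrib_s = (result.beta[:, :, None] * s.T[None]) ** 2
    var_dec = float(np.mean(contrib_d[ok]))
    var_sec = float(np.mean(contrib_s[ok]))
    total = var_dec + var_sec
    if total == 0:
        raise InvalidArgumentError("both explained variances are zero; fraction undefined")
    return var_dec, var_sec, var_dec / total


def synth_behavior(
    n_subjects: int,
    n_tests: int,
    alpha_true: float,
    beta_true: float,
    noise_sd: float,
    seed: int = 0,
    n_connections: int = 1,
    runs_per_subject: int = 2,
) -> tuple[np.ndarray, ECMetrics]:
    """Synthetic behavior + EC metrics with known coefficients.

    DEC and SEC are log-normal (nonnegative, right-skewed, like empirical EC
    metrics).  Each subject's metrics are duplicated across its runs and its
    single behavioral score is composed from connection ``i mod n_connections``
    for test i, plus Gaussian noise - reproducing the design in which one
    score per subject is used once per run.
    """
    if n_subjects < 1 or n_tests < 1 or n_connections < 1:
        raise InvalidArgumentError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    dec_subj = rng.lognormal(mean=0.0, sigma=0.5, size=(n_subjects, n_connections))
    sec_subj = rng.lognormal(mean=0.0, sigma=0.5, size=(n_subjects, n_connections))
    behavior = np.empty((n_subjects, n_tests))
    for i in range(n_tests):
        j = i % n_connections
        behavior[:, i] = (
            alpha_true * dec_subj[:, j]
            + beta_true * sec_subj[:, j]
            + noise_sd * rng.standard_normal(n_subjects)
        )
    dec = np.repeat(dec_subj, runs_per_subject, axis=0)
    sec = np.repeat(sec_subj, runs_per_subject, axis=0)
    return behavior, ECMetrics(dec=dec, sec=sec)
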