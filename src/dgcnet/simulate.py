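"""Ground-truthed time-varying MVAR simulator.

Generates lag-1 vector-autoregressive processes whose coefficient matrix has a
block-diagonal community structure over regions, in three regimes:

``constant``
    the coefficient matrix is fixed in time;
``sinusoidal``
    every nonzero coefficient oscillates as ``k * (1 + rho * sin(t/100 + phi))``
    with an independent random phase per entry (period 200*pi samples);
``shifting``
    the coefficient matrix is circularly shifted by one row and one column
    every 200 samples, so each region's community membership rotates.

The innovation covariance is the identity, the diagonal coefficients are
negative (low-pass behaviour, concentrating power at low frequencies), and the
spectral radius is kept below 1 at every time point so the process is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .containers import (
    InvalidArgumentError,
    SamplingFailureError,
    TimeSeriesMatrix,
    default_region_names,
)

SCENARIOS = ("constant", "sinusoidal", "shifting")

#: target spectral-radius ceiling after rescaling
_STABILITY_MARGIN = 0.95
#: sinusoidal modulation depth before any global rescale
_MODULATION_DEPTH = 0.5
#: samples between circular shifts in the ``shifting`` scenario
SHIFT_PERIOD = 200


@dataclass
class SimGroundTruth:
    """Everything the generator knows that an estimator must recover."""

    coeff_series: np.ndarray  # (T, R, R), source->target orientation
    noise_cov: np.ndarray  # (R, R)
    partition_series: np.ndarray  # (T, R) integer block labels
    scenario: str
    seed: int
    block_size: int = 3
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.region_names:
            self.region_names = default_region_names(self.coeff_series.shape[1])

    @property
    def n_time(self) -> int:
        return self.coeff_series.shape[0]

    @property
    def n_regions(self) -> int:
        return self.coeff_series.shape[1]


def _spectral_radius(mat: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(mat))))


def sample_stable_block_coeffs(
    n_regions: int,
    block_size: int,
    seed: int | np.random.Generator,
    max_retries: int = 100,
) -> np.ndarray:
    """Draw a stable block-diagonal lag-1 coefficient matrix.

    Diagonal entries are uniform on [-0.5, -0.1]; within-block off-diagonal
    entries have random sign and magnitude uniform on [0.3, 0.5] (bounded away
    from zero so every region is genuinely coupled to its block and every true
    edge sits above the sampling-noise floor of the recursive estimator: the
    block structure is then identifiable from data, as a validation scenario
    requires); entries outside the diagonal blocks are exactly zero.  If the
    draw is unstable it is rescaled to spectral radius 0.95, which preserves
    both the sparsity pattern and the diagonal sign.
    """
    if n_regions % block_size != 0:
        raise InvalidArgumentError(
            f"n_regions={n_regions} is not divisible by block_size={block_size}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_retries):
        coeffs = np.zeros((n_regions, n_regions))
        for start in range(0, n_regions, block_size):
            stop = start + block_size
            magnitude = rng.uniform(0.3, 0.5, size=(block_size, block_size))
            sign = rng.choice([-1.0, 1.0], size=(block_size, block_size))
            block = sign * magnitude
            np.fill_diagonal(block, rng.uniform(-0.5, -0.1, size=block_size))
            coeffs[start:stop, start:stop] = block
        radius = _spectral_radius(coeffs)
        if radius == 0.0:  # pragma: no cover - cannot happen with negative diagonal
            continue
        if radius > _STABILITY_MARGIN:
            coeffs *= _STABILITY_MARGIN / radius
        return coeffs
    raise SamplingFailureError("failed to sample a stable coefficient matrix")


def _block_partition(n_regions: int, block_size: int) -> np.ndarray:
    return np.repeat(np.arange(n_regions // block_size), block_size)


def _coeff_series(
    scenario: str,
    base: np.ndarray,
    n_time: int,
    block_size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Expand the base matrix into per-time coefficients and true partitions."""
    n_regions = base.shape[0]
    base_partition = _block_partition(n_regions, block_size)

    if scenario == "constant":
        series = np.broadcast_to(base, (n_time, n_regions, n_regions)).copy()
        partitions = np.broadcast_to(base_partition, (n_time, n_regions)).copy()
        return series, partitions

    if scenario == "sinusoidal":
        phases = rng.uniform(0.0, 2.0 * np.pi, size=base.shape)
        t = np.arange(n_time)[:, None, None]
        modulation = 1.0 + _MODULATION_DEPTH * np.sin(t / 100.0 + phases[None])
        series = base[None] * modulation
        max_radius = max(_spectral_radius(series[i]) for i in range(n_time))
        if max_radius > _STABILITY_MARGIN:
            series *= _STABILITY_MARGIN / max_radius
        if max(_spectral_radius(series[i]) for i in range(n_time)) >= 1.0:
            raise SamplingFailureError("modulated coefficient series remained unstable")
        partitions = np.broadcast_to(base_partition, (n_time, n_regions)).copy()
        return series, partitions

    if scenario == "shifting":
        series = np.empty((n_time, n_regions, n_regions))
        partitions = np.empty((n_time, n_regions), dtype=int)
        for t in range(n_time):
            shift = t // SHIFT_PERIOD
            series[t] = np.roll(base, (shift, shift), axis=(0, 1))
            partitions[t] = ((np.arange(n_regions) - shift) % n_regions) // block_size
        return series, partitions

    raise InvalidArgumentError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


def stationary_covariance(coeffs: np.ndarray, noise_cov: np.ndarray | None = None) -> np.ndarray:
    """Closed-form stationary covariance of ``z(t) = K^T z(t-1) + n(t)``.

    Solves the discrete Lyapunov equation ``S = A S A^T + Q`` with
    ``A = coeffs.T`` (coefficients are stored source->target).
    """
    n = coeffs.shape[0]
    q = np.eye(n) if noise_cov is None else noise_cov
    return solve_discrete_lyapunov(coeffs.T, q)


def simulate_scenario(
    scenario: str,
    n_time: int,
    n_regions: int = 12,
    seed: int = 0,
    block_size: int = 3,
) -> tuple[TimeSeriesMatrix, SimGroundTruth]:
    """Simulate one realization of a validation scenario.

    The initial state is drawn from the stationary distribution of the t=0
    model, so no internal burn-in is needed for the constant scenario.
    """
    if scenario not in SCENARIOS:
        raise InvalidArgumentError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if n_time < 1:
        raise InvalidArgumentError("n_time must be >= 1")
    rng = np.random.default_rng(seed)
    base = sample_stable_block_coeffs(n_regions, block_size, rng)
    series_coeffs, partitions = _coeff_series(scenario, base, n_time, block_size, rng)

    noise_cov = np.eye(n_regions)
    cov0 = stationary_covariance(series_coeffs[0], noise_cov)
    z = np.empty((n_time, n_regions))
    state = rng.multivariate_normal(np.zeros(n_regions), cov0, method="cholesky")
    noise = rng.standard_normal(size=(n_time, n_regions))
    for t in range(n_time):
        state = series_coeffs[t].T @ state + noise[t]
        z[t] = state

    truth = SimGroundTruth(
        coeff_series=series_coeffs,
        noise_cov=noise_cov,
        partition_series=partitions,
        scenario=scenario,
        seed=seed if isinstance(seed, int) else -1,
        block_size=block_size,
    )
    ts = TimeSeriesMatrix(values=z, region_names=list(truth.region_names))
    return ts, truth


def true_dgc_series(truth: SimGroundTruth) -> np.ndarray:
    """Squared ground-truth coefficients, (R, R, T): the target the DGC estimator tracks."""
    return np.transpose(truth.coeff_series**2, (1, 2, 0))
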