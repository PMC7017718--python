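"""Phase-randomization surrogate null for the symmetrized causality C.

Phase randomization preserves each region's amplitude spectrum (hence its
autocorrelation) while destroying the temporal structure *between* regions, so
causality estimated on surrogates samples a null distribution of "no directed
influence".  The chosen percentile of the pooled null C values is the
significance threshold th0 that anchors the sigmoid distance transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import InvalidArgumentError, TimeSeriesMatrix
from .distance import symmetrize_c
from .mvar import burn_in_trim, dgc, fit_dynamic_mvar


@dataclass
class NullDistribution:
    """Pooled null C samples and the derived threshold."""

    samples: np.ndarray
    n_surrogates: int
    percentile: float
    threshold: float
    seed: int | None = None
    per_connection: dict[tuple[int, int], float] = field(default_factory=dict)

    def summary_quantiles(self, qs=(5, 25, 50, 75, 95, 99)) -> dict[str, float]:
        return {f"q{q}": float(np.percentile(self.samples, q)) for q in qs}


def phase_randomize(
    series: TimeSeriesMatrix, seed: int | np.random.Generator = 0
) -> TimeSeriesMatrix:
    """Randomize each column's Fourier phases, keeping magnitudes exactly.

    Phases are drawn independently per column and per frequency bin; the DC
    component (and the Nyquist bin for even length) are left untouched so the
    inverse transform is real.
    """
    if series.n_time < 4:
        raise InvalidArgumentError("need at least 4 time points to phase-randomize")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = series.values
    t_total = values.shape[0]
    spectrum = np.fft.rfft(values, axis=0)
    n_bins = spectrum.shape[0]
    # bins whose phase may be freely randomized (exclude DC; exclude Nyquist if present)
    hi = n_bins - 1 if t_total % 2 == 0 else n_bins
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(hi - 1, values.shape[1]))
    randomized = spectrum.copy()
    randomized[1:hi] = np.abs(spectrum[1:hi]) * np.exp(1j * phases)
    out = np.fft.irfft(randomized, n=t_total, axis=0)
    return TimeSeriesMatrix(
        values=out,
        region_names=list(series.region_names),
        sampling_interval=series.sampling_interval,
    )


def build_null_threshold(
    series: TimeSeriesMatrix,
    n_surrogates: int = 1000,
    percentile: float = 95.0,
    dgc_settings: dict | None = None,
    seed: int = 0,
    pooled: bool = True,
) -> NullDistribution:
    """Monte-Carlo null distribution of C and its percentile threshold th0.

    Each surrogate is phase-randomized, the dynamic causality is recomputed
    with the same settings as the real analysis (order, forgetting, burn-in),
    the symmetrization is applied per time point, and off-diagonal C values are
    pooled across connections and times.  ``pooled=False`` additionally stores
    per-connection thresholds.
    """
    if n_surrogates < 1:
        raise InvalidArgumentError("n_surrogates must be >= 1")
    if not (0.0 < percentile <= 100.0):
        raise InvalidArgumentError("percentile must lie in (0, 100]")
    settings = dict(dgc_settings or {})
    order = int(settings.get("order", 1))
    forgetting = float(settings.get("forgetting", 0.05))
    burn_in = int(settings.get("burn_in", 50))
    m_exp = int(settings.get("m_exp", 2))
    n_exp = int(settings.get("n_exp", 1))

    rng = np.random.default_rng(seed)
    n_regions = series.n_regions
    off_mask = ~np.eye(n_regions, dtype=bool)
    pooled_samples = []
    per_conn_samples: list[np.ndarray] = []
    for _ in range(n_surrogates):
        surrogate = phase_randomize(series, rng)
        coeffs = fit_dynamic_mvar(surrogate, order, forgetting)
        tensor = burn_in_trim(dgc(coeffs), min(burn_in, coeffs.n_time - 1))
        c_stack = np.empty((tensor.n_time, n_regions, n_regions))
        for t in range(tensor.n_time):
            c_stack[t] = symmetrize_c(tensor.values[:, :, t], m_exp, n_exp)
        pooled_samples.append(c_stack[:, off_mask].ravel())
        if not pooled:
            per_conn_samples.append(c_stack)
    samples = np.concatenate(pooled_samples)
    threshold = float(np.percentile(samples, percentile))
    null = NullDistribution(
        samples=samples,
        n_surrogates=n_surrogates,
        percentile=percentile,
        threshold=threshold,
        seed=seed if isinstance(seed, int) else None,
    )
    if not pooled:
        stack = np.concatenate(per_conn_samples, axis=0)
        for i in range(n_regions):
            for j in range(n_regions):
                if i != j:
                    null.per_connection[(i, j)] = float(
                        np.percentile(stack[:, i, j], percentile)
                    )
    return null
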