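"""End-to-end orchestration: simulate/load -> DGC -> threshold -> distances ->
three clustering levels, with all intermediates written to disk.

Deterministic given the config (every stage's seed is spawned from the config
seed), and idempotent: re-running with the same config regenerates identical
outputs, including any intermediate that was deleted.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from . import io, level1, level2, level3, mvar, simulate, surrogate
from .distance import calibrate_sigmoid, distance_series

logger = logging.getLogger("dgcnet")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs up to that stage persist."""


def _spawn_seeds(seed: int, n: int) -> list[int]:
    # keep derived seeds below 2**31 for portability
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_pipeline(config: io.RunConfig, outdir: str | Path) -> dict:
    """Execute the full analysis described by ``config``; returns a result bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.to_yaml(outdir / "config.yaml")
    seeds = _spawn_seeds(config.seed, 4)
    bundle: dict = {"config_hash": chash}
    stage = "simulate"
    t0 = time.perf_counter()
    try:
        if config.input_path:
            series = io.read_timeseries(config.input_path, config.tr_seconds)
            truth = None
        else:
            series, truth = simulate.simulate_scenario(
                config.scenario,
                config.n_time,
                config.n_regions,
                seed=seeds[0],
            )
            io.write_timeseries(outdir / "series.tsv", series)
            io.write_json(
                outdir / "ground_truth.json",
                {
                    "scenario": truth.scenario,
                    "partition_series": truth.partition_series,
                    "coeff_series_first": truth.coeff_series[0],
                },
                chash,
            )
        _log_stage(stage, t0)

        stage = "order"
        t0 = time.perf_counter()
        order = (
            mvar.select_order_bic(series, config.max_order)
            if config.order == "auto"
            else int(config.order)
        )
        _log_stage(stage, t0)

        stage = "forgetting"
        t0 = time.perf_counter()
        forgetting = (
            mvar.optimize_forgetting(
                series, order, config.forgetting_grid, config.burn_in
            )
            if config.forgetting == "auto"
            else float(config.forgetting)
        )
        _log_stage(stage, t0)

        stage = "dgc"
        t0 = time.perf_counter()
        coeffs = mvar.fit_dynamic_mvar(series, order, forgetting)
        tensor = mvar.burn_in_trim(
            mvar.dgc(coeffs, list(series.region_names)), config.burn_in
        )
        io.save_dgc(outdir / "dgc", tensor)
        static = mvar.static_gc(mvar.fit_static_mvar(series, order))
        io.write_matrix(outdir / "static_gc.tsv", static, series.region_names)
        _log_stage(stage, t0)

        stage = "null-threshold"
        t0 = time.perf_counter()
        if config.th0 == "auto":
            null = surrogate.build_null_threshold(
                series,
                n_surrogates=config.n_surrogates,
                percentile=config.null_percentile,
                dgc_settings={
                    "order": order,
                    "forgetting": forgetting,
                    "burn_in": config.burn_in,
                    "m_exp": config.m_exp,
                    "n_exp": config.n_exp,
                },
                seed=seeds[1],
            )
            th0 = null.threshold
            io.write_json(
                outdir / "null_threshold.json",
                {
                    "threshold": th0,
                    "percentile": null.percentile,
                    "n_surrogates": null.n_surrogates,
                    "seed": seeds[1],
                    "quantiles": null.summary_quantiles(),
                },
                chash,
            )
        else:
            th0 = float(config.th0)
        _log_stage(stage, t0)

        stage = "distance"
        t0 = time.perf_counter()
        params = calibrate_sigmoid(th0, config.sigmoid_b, config.m_exp, config.n_exp)
        distances = distance_series(tensor, params)
        io.save_distances(outdir / "distances", distances)
        _log_stage(stage, t0)

        stage = "level1"
        t0 = time.perf_counter()
        alpha = (
            level1.select_alpha(distances, config.level1_alpha_grid)
            if config.level1_alpha == "auto"
            else float(config.level1_alpha)
        )
        partitions = level1.cluster_level1(distances, config.level1_k, alpha)
        io.write_labels(outdir / "level1_labels.tsv", partitions.labels)
        io.write_json(
            outdir / "level1_meta.json",
            {"alpha": alpha, "n_clusters": config.level1_k, "linkage": "average"},
            chash,
        )
        _log_stage(stage, t0)

        stage = "level2"
        t0 = time.perf_counter()
        k_range = list(range(2, min(config.level2_k_max, partitions.n_time - 1) + 1))
        result2 = level2.cluster_level2(
            partitions,
            distances,
            k_range=k_range,
            tr_seconds=config.tr_seconds,
            bin_width=config.dominance_bin_width,
        )
        mean_dwell, std_dwell, totals = level2.dwell_stats(
            result2.state_labels, config.tr_seconds
        )
        io.write_json(
            outdir / "level2.json",
            {
                "state_labels": result2.state_labels,
                "n_states": result2.n_states,
                "agents": {str(s): int(t) for s, (t, _) in result2.agents.items()},
                "occurrence_times": {str(k): v for k, v in result2.occurrence_times.items()},
                "dominant_states": result2.dominant_states,
                "dominance_threshold": result2.dominance_threshold,
                "silhouette": result2.silhouette,
                "dwell_mean_s": mean_dwell,
                "dwell_std_s": std_dwell,
                "time_per_state_desc_s": totals,
            },
            chash,
        )
        # Table-1-style per-run summary line
        with (outdir / "level2_summary.tsv").open("w") as fh:
            fh.write("n_states\tdwell_mean_s\tdwell_std_s\ttime_per_state_desc_s\n")
            fh.write(
                f"{result2.n_states}\t{mean_dwell:.2f}\t{std_dwell:.2f}\t"
                + ", ".join(f"{v:g}" for v in totals)
                + "\n"
            )
        _log_stage(stage, t0)

        stage = "level3"
        t0 = time.perf_counter()
        dominant = result2.dominant_states or list(result2.agents)
        vectors = [level3.vectorize_agent(result2.agents[s][1]) for s in dominant]
        weights = [result2.occurrence_times[s] for s in dominant]
        agents = level3.AgentSet(
            vectors=np.asarray(vectors),
            weights=np.asarray(weights, dtype=float),
            provenance=[("run0", int(s)) for s in dominant],
        )
        if config.level3_k == "auto" and agents.n_agents >= 4:
            k3 = None
            k_range3 = list(range(2, min(6, agents.n_agents - 1) + 1))
        else:
            k3 = 1 if config.level3_k == "auto" else int(config.level3_k)
            k_range3 = None
        result3 = level3.cluster_level3(
            agents, k=k3, k_range=k_range3, seed=seeds[2], restarts=config.level3_restarts
        )
        final_agent_idx = result3.agent_indices[result3.dominant_cluster]
        final_matrix = level3.devectorize_agent(
            agents.vectors[final_agent_idx], distances.n_regions
        )
        io.write_matrix(outdir / "level3_agent.tsv", final_matrix, distances.region_names)
        io.write_json(
            outdir / "level3.json",
            {
                "k": result3.k,
                "labels": result3.labels,
                "cluster_weights": {str(k): v for k, v in result3.cluster_weights.items()},
                "cluster_members": {str(k): v for k, v in result3.cluster_members.items()},
                "dominant_cluster": result3.dominant_cluster,
                "agent_indices": {str(k): v for k, v in result3.agent_indices.items()},
                "provenance": [list(p) for p in agents.provenance],
            },
            chash,
        )
        # Table-2-style summary: members and total occurrence times per cluster
        with (outdir / "level3_summary.tsv").open("w") as fh:
            fh.write("cluster\tn_members\ttotal_occurrence_times\n")
            for c in sorted(result3.cluster_members):
                fh.write(
                    f"{c + 1}\t{len(result3.cluster_members[c])}\t"
                    f"{result3.cluster_weights[c]:g}\n"
                )
            fh.write(
                f"sum\t{agents.n_agents}\t{float(agents.weights.sum()):g}\n"
            )
        _log_stage(stage, t0)
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise StageError(f"pipeline failed at stage '{stage}': {exc}") from exc

    bundle.update(
        {
            "order": order,
            "forgetting": forgetting,
            "th0": th0,
            "alpha": alpha,
            "level2": result2,
            "level3": result3,
            "truth": truth,
            "outdir": str(outdir),
        }
    )
    return bundle


def _log_stage(stage: str, t0: float) -> None:
    logger.info("stage %-14s finished in %.2fs", stage, time.perf_counter() - t0)
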