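"""File formats: delimited time-series matrices, array bundles, JSON sidecars.

Small outputs (partitions, static GC, summaries, configs) are plain text for
diffability; large arrays (DGC tensors, distance series) are stored as ``.npy``
with a JSON sidecar recording shape, region names, and provenance.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .containers import DGCTensor, TimeSeriesMatrix
from .distance import DistMatrixSeries, SigmoidParams


class ParseError(ValueError):
    """Malformed delimited input; the message names the offending line."""


def _detect_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_timeseries(path: str | Path, sampling_interval: float = 1.0) -> TimeSeriesMatrix:
    """Read a T x R delimited text matrix (tab or comma), optional header row."""
    path = Path(path)
    with path.open(newline="") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    delim = _detect_delimiter(lines[0])
    rows = list(csv.reader(lines, delimiter=delim))
    header: list[str] | None = None
    start = 0
    try:
        [float(cell) for cell in rows[0]]
    except ValueError:
        header = [cell.strip() for cell in rows[0]]
        start = 1
    width = len(rows[start]) if start < len(rows) else 0
    data = []
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if len(row) != width:
            raise ParseError(f"{path}: ragged row at line {lineno}")
        try:
            data.append([float(cell) for cell in row])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric cell at line {lineno}") from exc
    if not data:
        raise ParseError(f"{path}: no numeric rows")
    values = np.asarray(data)
    return TimeSeriesMatrix(
        values=values,
        region_names=header or [],
        sampling_interval=sampling_interval,
    )


def write_timeseries(path: str | Path, series: TimeSeriesMatrix) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(series.region_names) + "\n")
        for row in series.values:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def write_matrix(path: str | Path, matrix: np.ndarray, names: list[str] | None = None) -> None:
    """Tab-delimited square matrix, optionally with a header row."""
    with Path(path).open("w") as fh:
        if names:
            fh.write("\t".join(names) + "\n")
        for row in np.atleast_2d(matrix):
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Tab-delimited integer label matrix (T rows, R columns)."""
    with Path(path).open("w") as fh:
        for row in np.atleast_2d(labels):
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_labels(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=int, ndmin=2)


def save_dgc(prefix: str | Path, tensor: DGCTensor) -> None:
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), tensor.values)
    sidecar = {
        "shape": list(tensor.values.shape),
        "region_names": tensor.region_names,
        "burn_in_removed": tensor.burn_in_removed,
        "burn_in_length": tensor.burn_in_length,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_dgc(prefix: str | Path) -> DGCTensor:
    prefix = Path(prefix)
    values = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return DGCTensor(
        values=values,
        burn_in_removed=meta["burn_in_removed"],
        burn_in_length=meta["burn_in_length"],
        region_names=meta["region_names"],
    )


def save_distances(prefix: str | Path, series: DistMatrixSeries) -> None:
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), series.matrices)
    sidecar: dict[str, Any] = {
        "shape": list(series.matrices.shape),
        "region_names": series.region_names,
    }
    if series.params is not None:
        sidecar["params"] = asdict(series.params)
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_distances(prefix: str | Path) -> DistMatrixSeries:
    prefix = Path(prefix)
    matrices = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    params = SigmoidParams(**meta["params"]) if "params" in meta else None
    return DistMatrixSeries(
        matrices=matrices, region_names=meta["region_names"], params=params
    )


@dataclass
class RunConfig:
    """Pipeline configuration; every random stage derives its seed from ``seed``."""

    seed: int = 0
    scenario: str = "shifting"
    n_time: int = 1000
    n_regions: int = 12
    tr_seconds: float = 1.0
    order: int | str = "auto"  # "auto" -> BIC
    max_order: int = 5
    forgetting: float | str = "auto"  # "auto" -> grid search
    forgetting_grid: tuple = (0.01, 0.02, 0.05, 0.10, 0.15, 0.20)
    burn_in: int = 50
    n_surrogates: int = 100
    null_percentile: float = 95.0
    th0: float | str = "auto"  # "auto" -> surrogate threshold
    sigmoid_b: float = 0.2
    m_exp: int = 2
    n_exp: int = 1
    level1_k: int = 6
    level1_alpha: float | str = "auto"
    level1_alpha_grid: tuple = (0.0, 0.2, 0.4, 0.6, 0.8)
    level2_k_max: int = 20
    dominance_bin_width: int = 5
    level3_k: int | str = "auto"
    level3_restarts: int = 10
    input_path: str | None = None  # load instead of simulate

    def to_dict(self) -> dict:
        d = asdict(self)
        d["forgetting_grid"] = list(d["forgetting_grid"])
        d["level1_alpha_grid"] = list(d["level1_alpha_grid"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("forgetting_grid", "level1_alpha_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_json(path: str | Path, payload: dict, config_hash: str | None = None) -> None:
    if config_hash is not None:
        payload = {**payload, "config_hash": config_hash}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
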