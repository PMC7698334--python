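"""Binned feature vectors/matrices and their CSV representation.

A feature is one spectral bin: the sum of a fixed number of consecutive
spectral points, identified by its ppm interval ``(high, low)``.  Vectors
carry a stage marker recording how far through the preprocessing chain
(binned -> region_selected -> normalized -> log2) they have travelled, so
stage preconditions can be enforced instead of silently recomputed.

The matrix CSV is RFC-4180, UTF-8, '.' decimals: first column ``sample_id``,
then one column per bin labelled ``ppm_<high>_<low>`` (full ``repr``
precision so files round-trip bit-for-bit), last column ``label``.  The
stage marker is not stored in the file; callers supply it on read (default
``log2``, the stage of a fully preprocessed matrix).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FeatureMatrixError, InvalidParameterError

STAGE_BINNED = "binned"
STAGE_REGION = "region_selected"
STAGE_NORMALIZED = "normalized"
STAGE_LOG2 = "log2"
STAGES = (STAGE_BINNED, STAGE_REGION, STAGE_NORMALIZED, STAGE_LOG2)

_VALID_LABELS = ("IDHmut", "IDHwt", "unknown")


def _check_bin_edges(bin_edges) -> list[tuple[float, float]]:
    edges = [(float(hi), float(lo)) for hi, lo in bin_edges]
    for hi, lo in edges:
        if not hi > lo:
            raise InvalidParameterError(f"bin edge ({hi}, {lo}) is not a (high, low) ppm pair")
    for (_, lo_prev), (hi_next, _) in zip(edges, edges[1:]):
        if hi_next > lo_prev + 1e-9:
            raise InvalidParameterError("bins must be non-overlapping and decreasing in ppm")
    return edges


@dataclass
class FeatureVector:
    """Binned intensities of one sample with their ppm intervals."""

    values: np.ndarray
    bin_edges: list[tuple[float, float]]
    sample_id: str = ""
    label: str = "unknown"
    stage: str = STAGE_BINNED

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.bin_edges = _check_bin_edges(self.bin_edges)
        if self.values.ndim != 1 or len(self.values) != len(self.bin_edges):
            raise InvalidParameterError(
                f"{len(self.values)} values but {len(self.bin_edges)} bin edges"
            )
        if self.stage not in STAGES:
            raise InvalidParameterError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.label not in _VALID_LABELS:
            raise InvalidParameterError(f"label must be one of {_VALID_LABELS}")

    @property
    def bin_midpoints(self) -> np.ndarray:
        return np.array([(hi + lo) / 2.0 for hi, lo in self.bin_edges])


@dataclass
class FeatureMatrix:
    """Samples x bins matrix with ids, labels and bin ppm intervals."""

    values: np.ndarray
    bin_edges: list[tuple[float, float]]
    sample_ids: list[str]
    labels: list[str]
    stage: str = STAGE_LOG2
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InvalidParameterError("feature matrix must be 2-D")
        self.bin_edges = _check_bin_edges(self.bin_edges)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise InvalidParameterError("sample_ids/labels length must match row count")
        if len(self.bin_edges) != p:
            raise InvalidParameterError("bin_edges length must match column count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FeatureMatrixError("duplicated sample_id in feature matrix")
        bad = [l for l in self.labels if l not in _VALID_LABELS]
        if bad:
            raise FeatureMatrixError(f"label(s) outside {_VALID_LABELS}: {sorted(set(bad))}")
        if self.stage not in STAGES:
            raise InvalidParameterError(f"stage must be one of {STAGES}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def bin_midpoints(self) -> np.ndarray:
        return np.array([(hi + lo) / 2.0 for hi, lo in self.bin_edges])

    def row(self, i: int) -> FeatureVector:
        return FeatureVector(
            self.values[i].copy(), list(self.bin_edges),
            sample_id=self.sample_ids[i], label=self.labels[i], stage=self.stage,
        )

    @classmethod
    def from_rows(cls, rows: list[FeatureVector], meta: dict | None = None) -> "FeatureMatrix":
        if not rows:
            raise InvalidParameterError("cannot build a matrix from zero rows")
        edges = rows[0].bin_edges
        stage = rows[0].stage
        for r in rows[1:]:
            if r.bin_edges != edges or r.stage != stage:
                raise FeatureMatrixError("rows differ in bin edges or stage")
        return cls(
            np.vstack([r.values for r in rows]), list(edges),
            [r.sample_id for r in rows], [r.label for r in rows],
            stage=stage, meta=meta or {},
        )


def _bin_column_label(hi: float, lo: float) -> str:
    return f"ppm_{hi!r}_{lo!r}"


def _parse_bin_column(name: str) -> tuple[float, float]:
    if not name.startswith("ppm_"):
        raise FeatureMatrixError(f"unexpected feature column name {name!r}")
    try:
        hi_s, lo_s = name[4:].split("_")
        return float(hi_s), float(lo_s)
    except ValueError as exc:
        raise FeatureMatrixError(f"cannot parse bin interval from column {name!r}") from exc


def write_feature_matrix_csv(matrix: FeatureMatrix, path: str | os.PathLike) -> None:
    """Write the matrix as RFC-4180 CSV (full float precision)."""
    df = pd.DataFrame(
        matrix.values,
        columns=[_bin_column_label(hi, lo) for hi, lo in matrix.bin_edges],
    )
    df.insert(0, "sample_id", matrix.sample_ids)
    df["label"] = matrix.labels
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_feature_matrix_csv(path: str | os.PathLike, stage: str = STAGE_LOG2) -> FeatureMatrix:
    """Read a feature-matrix CSV written by :func:`write_feature_matrix_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "sample_id" or df.columns[-1] != "label":
        raise FeatureMatrixError(
            f"{path}: first column must be 'sample_id' and last column 'label'"
        )
    bin_cols = list(df.columns[1:-1])
    edges = [_parse_bin_column(c) for c in bin_cols]
    values = df[bin_cols].to_numpy(dtype=np.float64) if bin_cols else np.empty((len(df), 0))
    return FeatureMatrix(
        values, edges, list(df["sample_id"].astype(str)), list(df["label"].astype(str)),
        stage=stage,
    )
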