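"""Tabular containers and plain-text I/O.

Expression matrices are TSV with a ``gene_id`` first column and remaining
columns labelled by sampling time in hours; activity traces are tidy CSV
(individual, population, group, hour_index, distance).  Floats are written
with 12 significant digits so that write -> read -> write round-trips are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "ActivityTrace",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_activity_traces",
    "write_activity_traces",
    "load_yaml_config",
]

FLOAT_FMT = "%.12g"


class ValidationError(ValueError):
    """Raised when an input table violates the expected layout or contents."""


@dataclass
class ExpressionMatrix:
    """Genes x timepoints TPM matrix on a uniform time grid.

    ``tpm`` is indexed by gene id with float column labels in hours.
    """

    tpm: pd.DataFrame
    population: str = ""
    group: str = ""

    def __post_init__(self):
        self.tpm.columns = [float(c) for c in self.tpm.columns]
        self.validate()

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.tpm.columns, dtype=float)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.tpm.index.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.tpm.shape[0]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def validate(self) -> None:
        t = self.times
        if len(t) < 2:
            raise ValidationError("need at least 2 timepoints")
        diffs = np.diff(t)
        if np.any(diffs <= 0):
            raise ValidationError("timepoints must be strictly increasing")
        if not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-9):
            raise ValidationError(
                f"non-uniform time grid: spacings range {diffs.min()}–{diffs.max()} h"
            )
        if self.tpm.index.duplicated().any():
            dup = self.tpm.index[self.tpm.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        vals = self.tpm.to_numpy()
        if np.isnan(vals).any():
            g, c = np.argwhere(np.isnan(vals))[0]
            raise ValidationError(
                f"missing value for gene {self.tpm.index[g]!r} at t={t[c]} h"
            )
        if (vals < 0).any():
            g, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative TPM for gene {self.tpm.index[g]!r} at t={t[c]} h"
            )


@dataclass
class ActivityTrace:
    """Hourly locomotor distance series for one individual."""

    individual_id: str
    distances: np.ndarray
    population: str = ""
    group: str = ""
    t0: float = 0.0

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if (self.distances < 0).any():
            raise ValidationError(
                f"negative hourly distance for individual {self.individual_id!r}"
            )

    @property
    def hours(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.distances), dtype=float)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.tpm.copy()
    df.columns = [FLOAT_FMT % t for t in matrix.times]
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_expression_matrix(path, population: str = "", group: str = "") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        cols = [float(c) for c in df.columns]
    except ValueError as err:
        raise ValidationError(f"non-numeric time column label: {err}") from None
    df.columns = cols
    for col in cols:
        bad = df[col].isna()
        if bad.any():
            raise ValidationError(
                f"missing value for gene {df.index[bad.argmax()]!r} at t={col} h"
            )
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValidationError(f"non-numeric entries in column t={col} h")
    return ExpressionMatrix(df, population=population, group=group)


def write_activity_traces(traces, path) -> None:
    rows = []
    for tr in traces:
        for k, dist in enumerate(tr.distances):
            rows.append((tr.individual_id, tr.population, tr.group, k, dist))
    df = pd.DataFrame(rows, columns=["individual", "population", "group",
                                     "hour_index", "distance"])
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_activity_traces(path) -> list:
    df = pd.read_csv(path)
    required = {"individual", "hour_index", "distance"}
    if not required <= set(df.columns):
        raise ValidationError(f"trace CSV must have columns {sorted(required)}")
    traces = []
    for ind, sub in df.groupby("individual", sort=True):
        sub = sub.sort_values("hour_index")
        if not np.array_equal(sub["hour_index"].to_numpy(),
                              np.arange(len(sub))):
            raise ValidationError(
                f"individual {ind!r}: hour_index must be 0..n-1 without gaps"
            )
        traces.append(ActivityTrace(
            individual_id=str(ind),
            distances=sub["distance"].to_numpy(dtype=float),
            population=str(sub["population"].iloc[0]) if "population" in sub else "",
            group=str(sub["group"].iloc[0]) if "group" in sub else "",
        ))
    return traces


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config file must contain a mapping")
    return cfg
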