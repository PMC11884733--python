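"""Fixed-length per-patient feature extraction from cluster properties.

Each of the 11 network properties contributes the summary statistics
min, Q1, median, mean, Q3, max of its per-cluster values; the four
properties that can be NA on degenerate clusters (assortativity,
transitivity, closeness centralization, central eigenvector) additionally
contribute prob(NA).  This yields exactly 70 columns in 11 groups of
sizes (6,6,6,6,7,7,6,6,7,6,7), independent of how many clusters a
patient has -- which is what makes cross-patient modelling possible.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import CAUSAL_PROPERTIES, NA_PROPERTIES, PROPERTY_ORDER, ClusterPropertyTable

logger = logging.getLogger(__name__)

LOCATION_STATS = ("min", "q1", "median", "mean", "q3", "max")


@dataclass(frozen=True)
class PropertySchema:
    """Ordered property list and which properties carry a prob(NA) statistic."""

    properties: tuple[str, ...] = PROPERTY_ORDER
    na_properties: frozenset[str] = NA_PROPERTIES

    def stats_for(self, prop: str) -> tuple[str, ...]:
        if prop in self.na_properties:
            return ("prob_na",) + LOCATION_STATS
        return LOCATION_STATS

    def column_labels(self) -> list[str]:
        return [
            f"{prop}__{stat}" for prop in self.properties for stat in self.stats_for(prop)
        ]

    def group_sizes(self) -> list[int]:
        return [len(self.stats_for(p)) for p in self.properties]

    @property
    def n_columns(self) -> int:
        return sum(self.group_sizes())


@dataclass
class GroupSpec:
    """Column -> group mapping for the grouped penalty."""

    names: list[str]
    sizes: list[int]

    def __post_init__(self):
        if len(self.names) != len(self.sizes):
            raise ValueError("names and sizes must align")
        if any(s < 1 for s in self.sizes):
            raise ValueError("group sizes must be >= 1")

    @property
    def G(self) -> int:
        return len(self.sizes)

    @property
    def P(self) -> int:
        return int(sum(self.sizes))

    @property
    def starts(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.sizes)[:-1]]).astype(int)

    def group_of(self) -> np.ndarray:
        """Length-P vector of group ids (0-based)."""
        return np.repeat(np.arange(self.G), self.sizes)

    def columns_of(self, g: int) -> np.ndarray:
        start = self.starts[g]
        return np.arange(start, start + self.sizes[g])

    def to_json(self, path: str | Path) -> None:
        mapping = {
            name: [int(c) for c in self.columns_of(g)]
            for g, name in enumerate(self.names)
        }
        Path(path).write_text(json.dumps(mapping, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroupSpec":
        mapping = json.loads(Path(path).read_text())
        names = list(mapping)
        sizes = [len(cols) for cols in mapping.values()]
        return cls(names=names, sizes=sizes)


@dataclass
class FeatureMatrix:
    """n_patients x P design with labelled columns and optional z-scoring state."""

    values: np.ndarray
    columns: list[str]
    patients: list[str]
    imputed: list[tuple[str, str]] = field(default_factory=list)
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patients), len(self.columns)):
            raise ValueError("values shape does not match labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patients, columns=self.columns)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("patient_id").to_csv(path)


def summarize_property(values, has_na_stat: bool) -> list[float]:
    """Summary statistics over the non-NA entries of one property.

    Quantiles use linear interpolation of order statistics.  If every
    entry is NA the six location statistics come back NaN (imputed later
    across patients); prob(NA) is always well defined.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty value list")
    na_mask = np.isnan(vals)
    prob_na = float(na_mask.mean())
    finite = vals[~na_mask]
    if finite.size == 0:
        loc = [math.nan] * 6
    else:
        loc = [
            float(finite.min()),
            float(np.quantile(finite, 0.25)),
            float(np.quantile(finite, 0.5)),
            float(finite.mean()),
            float(np.quantile(finite, 0.75)),
            float(finite.max()),
        ]
    return [prob_na] + loc if has_na_stat else loc


def patient_feature_row(
    table: ClusterPropertyTable, schema: PropertySchema = PropertySchema()
) -> list[float]:
    if len(table) == 0:
        raise ValueError(f"patient {table.patient_id!r} has no retained clusters")
    row: list[float] = []
    for prop in schema.properties:
        row.extend(
            summarize_property(
                table.property_values(prop), has_na_stat=prop in schema.na_properties
            )
        )
    return row


def build_feature_matrix(
    tables: list[ClusterPropertyTable], schema: PropertySchema = PropertySchema()
) -> tuple[FeatureMatrix, GroupSpec]:
    """Aggregate per-patient cluster property tables into the fixed design.

    All-NA cells (e.g. a patient whose clusters are all 2-node, so a
    NA-prone property has no finite value) are imputed with the column
    median across patients and flagged in ``FeatureMatrix.imputed``.
    """
    if not tables:
        raise ValueError("need at least one patient table")
    rows = [patient_feature_row(t, schema) for t in tables]
    values = np.asarray(rows, dtype=float)
    columns = schema.column_labels()
    patients = [t.patient_id for t in tables]

    imputed: list[tuple[str, str]] = []
    for j, col in enumerate(columns):
        nan_rows = np.isnan(values[:, j])
        if nan_rows.any():
            med = np.nanmedian(values[:, j]) if not nan_rows.all() else 0.0
            for i in np.flatnonzero(nan_rows):
                imputed.append((patients[i], col))
            values[nan_rows, j] = med

    spec = GroupSpec(names=list(schema.properties), sizes=schema.group_sizes())
    fm = FeatureMatrix(values=values, columns=columns, patients=patients, imputed=imputed)
    return fm, spec


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Column-wise z-score (sample sd, n-1); constant columns become zero."""
    if fm.shape[0] < 2:
        raise ValueError("standardization needs at least 2 patients")
    if np.isnan(fm.values).any():
        raise ValueError("standardize requires a complete matrix (impute first)")
    center = fm.values.mean(axis=0)
    scale = fm.values.std(axis=0, ddof=1)
    constant = scale == 0
    if constant.any():
        logger.warning(
            "%d constant feature column(s) set to zero: %s",
            constant.sum(),
            [fm.columns[j] for j in np.flatnonzero(constant)][:5],
        )
        scale = np.where(constant, 1.0, scale)
    z = (fm.values - center) / scale
    return FeatureMatrix(
        values=z,
        columns=list(fm.columns),
        patients=list(fm.patients),
        imputed=list(fm.imputed),
        center=center,
        scale=scale,
    )


def causal_column_mask(
    schema: PropertySchema = PropertySchema(),
    causal_properties: tuple[str, ...] = CAUSAL_PROPERTIES,
) -> np.ndarray:
    """Boolean mask over the schema columns marking the causal properties'
    features (25 columns with the default schema)."""
    mask = []
    for prop in schema.properties:
        mask.extend([prop in causal_properties] * len(schema.stats_for(prop)))
    return np.asarray(mask, dtype=bool)
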