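"""Expression-matrix containers, quantile normalization, and log2 transform.

Single-channel array intensities arrive on a linear positive scale with a
two-level group factor (case/control).  Normalization forces every sample
column onto one common empirical distribution (the per-rank across-sample
means); testing and correlation then run on log2 values while fold changes
are taken from linear normalized means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")
MOLECULE_TYPES = ("lncRNA", "mRNA")


@dataclass
class ExpressionMatrix:
    """Probes x samples intensity matrix with group labels.

    ``values`` is a DataFrame indexed by probe id with sample-id columns.
    ``groups`` maps every sample id to ``case`` or ``control``.
    ``scale`` tags the data as ``linear`` (strictly positive) or ``log2``.
    """

    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = {g for g in self.groups.values() if g not in GROUPS}
        if bad:
            raise ValueError(f"group labels must be in {GROUPS}, got {sorted(bad)}")
        for g in GROUPS:
            if not any(v == g for v in self.groups.values()):
                raise ValueError(f"group {g!r} has no samples")
        if self.scale == "linear" and not (self.values.to_numpy() > 0).all():
            raise ValueError("linear-scale intensities must be strictly positive")

    # -- convenience accessors -------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def subset(self, probe_ids) -> "ExpressionMatrix":
        """Row-subset preserving the requested probe order."""
        return replace(self, values=self.values.loc[list(probe_ids)])

    # -- TSV dialect -----------------------------------------------------------

    def to_tsv(self, path, groups_path) -> None:
        """Write the matrix (first column ``probe_id``) and the group sidecar."""
        out = self.values.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", float_format="%.10g")
        pd.DataFrame(
            {"sample_id": list(self.values.columns),
             "group": [self.groups[s] for s in self.values.columns]}
        ).to_csv(groups_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, groups_path, scale: str = "linear") -> "ExpressionMatrix":
        """Load matrix + sidecar; probe rows with any missing value are dropped."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        n_bad = int(df.isna().any(axis=1).sum())
        if n_bad:
            logger.warning("dropping %d probe row(s) with missing values", n_bad)
            df = df.dropna(axis=0)
        grp = pd.read_csv(groups_path, sep="\t")
        groups = dict(zip(grp["sample_id"].astype(str), grp["group"]))
        df.columns = df.columns.astype(str)
        return cls(values=df.astype(float), groups=groups, scale=scale)


@dataclass
class ProbeAnnotation:
    """Probe id -> molecule type (lncRNA|mRNA) and gene symbol."""

    table: pd.DataFrame  # columns: probe_id, molecule_type, gene_symbol

    def __post_init__(self) -> None:
        required = ["probe_id", "molecule_type", "gene_symbol"]
        if list(self.table.columns)[:3] != required:
            raise ValueError(f"annotation columns must be {required}")
        if self.table["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids in annotation")
        bad = set(self.table["molecule_type"]) - set(MOLECULE_TYPES)
        if bad:
            raise ValueError(f"molecule_type must be in {MOLECULE_TYPES}, got {sorted(bad)}")

    def probes_of_type(self, molecule_type: str) -> list[str]:
        mask = self.table["molecule_type"] == molecule_type
        return list(self.table.loc[mask, "probe_id"])

    @property
    def symbol_of(self) -> dict[str, str]:
        return dict(zip(self.table["probe_id"], self.table["gene_symbol"]))

    @property
    def molecule_type_of(self) -> dict[str, str]:
        return dict(zip(self.table["probe_id"], self.table["molecule_type"]))

    def mrna_universe(self) -> frozenset[str]:
        """Gene symbols carried by annotated mRNA probes (enrichment background)."""
        mask = self.table["molecule_type"] == "mRNA"
        return frozenset(self.table.loc[mask, "gene_symbol"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ProbeAnnotation":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the per-rank across-sample mean distribution.

    After normalization each column holds the identical multiset of values
    (the rank means of the input) and within-column rank order is preserved.
    Tied input values receive the mean of the rank-means their positions span
    (average-ties dialect), making the result deterministic and
    order-independent.
    """
    if m.scale != "linear":
        raise ValueError("quantile normalization expects linear-scale intensities")
    X = m.values.to_numpy(dtype=float)
    n_probes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if not (X > 0).all():
        raise ValueError("non-positive intensities")

    rank_means = np.sort(X, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(rank_means)])
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        _, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        group_means = (csum[starts + counts] - csum[starts]) / counts
        out[:, j] = group_means[inv]

    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=values, groups=dict(m.groups), scale="linear")


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2 the matrix; refuses to double-transform."""
    if m.scale == "log2":
        raise ValueError("matrix is already log2-scaled")
    if not (m.values.to_numpy() > 0).all():
        raise ValueError("log2 transform requires strictly positive values")
    return ExpressionMatrix(values=np.log2(m.values), groups=dict(m.groups), scale="log2")


def as_log2(m: ExpressionMatrix) -> ExpressionMatrix:
    return m if m.scale == "log2" else log2_transform(m)


def as_linear(m: ExpressionMatrix) -> ExpressionMatrix:
    if m.scale == "linear":
        return m
    return ExpressionMatrix(values=np.exp2(m.values), groups=dict(m.groups), scale="linear")
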