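"""Differential-expression screening, top-k selection, and cluster ordering.

Screening follows the classic single-channel array recipe: an unpaired
two-sample t-test on log2 intensities combined with a linear-scale
fold-change gate.  A probe is called significant when its fold-change
magnitude reaches ``fc_min`` (default 2.0) and its p-value is at most
``p_max`` (default 0.05).  Fold change is reported as a magnitude >= 1
plus an up/down direction, so a 4-fold drop is FC 4.0 "down".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from lncnet.preprocess import ExpressionMatrix, ProbeAnnotation, as_linear, as_log2

logger = logging.getLogger(__name__)


@dataclass
class DERecord:
    """Per-probe differential-expression result."""

    probe_id: str
    mean_case: float
    mean_control: float
    fold_change: float  # magnitude >= 1
    direction: str      # 'up' iff mean_case > mean_control
    p_value: float
    significant: bool
    q_value: Optional[float] = None  # BH-adjusted p, when requested


@dataclass
class ClusterOrder:
    """Leaf ordering plus the merge tree from agglomerative clustering."""

    ordered_ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix, (n-1) x 4


def differential_expression(
    m: ExpressionMatrix,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    welch: bool = False,
    bh: bool = False,
) -> list[DERecord]:
    """Screen every probe by t-test (log2 scale) and fold change (linear scale).

    Parameters
    ----------
    m
        Normalized expression matrix, either scale tag; converted as needed.
    welch
        Use the unequal-variance (Welch) t-test instead of pooled Student.
    bh
        Gate significance on Benjamini-Hochberg adjusted p-values instead of
        raw ones; raw p is still reported, the adjusted value in ``q_value``.
    """
    case = m.samples_in("case")
    control = m.samples_in("control")
    if len(case) < 2 or len(control) < 2:
        raise ValueError("both groups need at least 2 samples for a t-test")

    lin = as_linear(m).values
    logm = as_log2(m).values
    mean_case = lin[case].mean(axis=1).to_numpy()
    mean_control = lin[control].mean(axis=1).to_numpy()

    a = logm[case].to_numpy()
    b = logm[control].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant rows trip scipy's precision-loss warning; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)

    # Degenerate rows: zero variance in both groups. Equal means carry no
    # evidence (p := 1); distinct constant means are unambiguous (p := 0).
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        logger.warning("%d probe(s) with zero within-group variance", int(degenerate.sum()))
        eq = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(degenerate, np.where(eq, 1.0, 0.0), p)
    p = np.nan_to_num(p, nan=1.0)

    with np.errstate(divide="ignore"):
        ratio = mean_case / mean_control
    fold = np.maximum(ratio, 1.0 / ratio)
    direction = np.where(mean_case > mean_control, "up", "down")

    if bh:
        q = _bh_adjust(p)
        signif = (fold >= fc_min) & (q <= p_max)
    else:
        q = None
        signif = (fold >= fc_min) & (p <= p_max)

    records = []
    for i, probe in enumerate(m.probe_ids):
        records.append(
            DERecord(
                probe_id=probe,
                mean_case=float(mean_case[i]),
                mean_control=float(mean_control[i]),
                fold_change=float(fold[i]),
                direction=str(direction[i]),
                p_value=float(p[i]),
                significant=bool(signif[i]),
                q_value=float(q[i]) if q is not None else None,
            )
        )
    return records


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _selection_key(r: DERecord):
    # total deterministic order: ascending p, descending FC, ascending id
    return (r.p_value, -r.fold_change, r.probe_id)


def select_top_k(
    records: Iterable[DERecord], k_up: int, k_down: int
) -> tuple[list[DERecord], list[DERecord]]:
    """Pick the k_up / k_down most significant probes per direction.

    Ordering is ascending p, then descending fold change, then probe id —
    a total order, so the selection is stable under input permutation.
    Returns fewer than requested (with a warning) when the significant set
    is too small.
    """
    if k_up < 0 or k_down < 0:
        raise ValueError("k_up and k_down must be non-negative")
    sig = [r for r in records if r.significant]
    up = sorted((r for r in sig if r.direction == "up"), key=_selection_key)
    down = sorted((r for r in sig if r.direction == "down"), key=_selection_key)
    if len(up) < k_up or len(down) < k_down:
        logger.warning(
            "requested top %d up / %d down but only %d / %d significant",
            k_up, k_down, len(up), len(down),
        )
    return up[:k_up], down[:k_down]


def hierarchical_cluster(m: ExpressionMatrix, probes: Sequence[str]) -> ClusterOrder:
    """Average-linkage agglomeration on 1 - Pearson r over standardized log2 rows.

    Constant rows have undefined correlation; their distance to every other
    row is defined as 1 (r treated as 0) and logged.
    """
    probes = list(probes)
    if len(probes) < 2:
        raise ValueError("clustering needs at least 2 probes")
    X = as_log2(m).subset(probes).values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    n_const = int((sd == 0).sum())
    if n_const:
        logger.warning("%d constant probe row(s); correlation distance set to 1", n_const)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = pdist(X, metric="correlation")
    d = np.nan_to_num(d, nan=1.0)
    Z = hierarchy.linkage(d, method="average")
    order = hierarchy.leaves_list(Z)
    return ClusterOrder(ordered_ids=[probes[i] for i in order], linkage=Z)


def de_table(records: Sequence[DERecord], annotation: Optional[ProbeAnnotation] = None) -> pd.DataFrame:
    """Flatten DE records to the exported TSV layout."""
    df = pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "mean_case": [r.mean_case for r in records],
            "mean_control": [r.mean_control for r in records],
            "fold_change": [r.fold_change for r in records],
            "direction": [r.direction for r in records],
            "p_value": [r.p_value for r in records],
            "significant": [r.significant for r in records],
        }
    )
    if records and records[0].q_value is not None:
        df["q_value"] = [r.q_value for r in records]
    if annotation is not None:
        mt = annotation.molecule_type_of
        df.insert(1, "molecule_type", [mt.get(p, "") for p in df["probe_id"]])
    return df
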