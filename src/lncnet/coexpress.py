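"""Signed lncRNA-mRNA coexpression edges by Pearson correlation.

Edges are called across all samples pooled (both groups), which is what
lets a strong group contrast drive coexpression; with three arrays per
group that gives n = 6 points per correlation.  An edge is retained when
|r| >= r_min (default 0.7, inclusive, on the magnitude — anticorrelated
pairs become negative edges) and its two-sided p-value is at most p_max
(default 0.05); a p-only mode drops the |r| gate for the
function-prediction partner sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lncnet.preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationEdge:
    lnc_id: str
    mrna_id: str
    r: float
    p_value: float
    sign: str  # 'positive' iff r > 0


def _corr_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via t = r*sqrt((n-2)/(1-r^2)) on n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson coefficient with its two-sided t-distribution p-value.

    Constant input has no defined correlation: returns (0.0, 1.0) with a
    warning so such a pair can never become an edge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    if x.std() == 0 or y.std() == 0:
        logger.warning("constant vector: correlation undefined, returning r=0, p=1")
        return 0.0, 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return r, float(_corr_p(np.array(r), n))


def build_edges(
    lnc: ExpressionMatrix,
    mrna: ExpressionMatrix,
    r_min: float = 0.7,
    p_max: float = 0.05,
    p_only: bool = False,
) -> list[CorrelationEdge]:
    """Evaluate every lncRNA x mRNA pair; retain significant correlated pairs.

    Both matrices must share the identical sample order.  Returns edges in
    deterministic row-major (lnc, mrna) order.  Constant probes are treated
    as r = 0 and never retained.
    """
    if lnc.sample_ids != mrna.sample_ids:
        raise ValueError("lncRNA and mRNA matrices must share sample order")
    n = len(lnc.sample_ids)
    A = lnc.values.to_numpy(dtype=float)
    B = mrna.values.to_numpy(dtype=float)

    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    const_a, const_b = na == 0, nb == 0
    if const_a.any() or const_b.any():
        logger.warning(
            "%d lncRNA and %d mRNA constant probe(s); their correlations set to 0",
            int(const_a.sum()), int(const_b.sum()),
        )
    na[const_a] = 1.0
    nb[const_b] = 1.0
    R = (A / na[:, None]) @ (B / nb[:, None]).T
    R[const_a, :] = 0.0
    R[:, const_b] = 0.0
    R = np.clip(R, -1.0, 1.0)
    P = _corr_p(R, n)

    keep = P <= p_max
    if not p_only:
        keep &= np.abs(R) >= r_min
    keep &= R != 0.0  # r == 0 carries no sign and never indicates coexpression

    lnc_ids, mrna_ids = lnc.probe_ids, mrna.probe_ids
    edges = [
        CorrelationEdge(
            lnc_id=lnc_ids[i],
            mrna_id=mrna_ids[j],
            r=float(R[i, j]),
            p_value=float(P[i, j]),
            sign="positive" if R[i, j] > 0 else "negative",
        )
        for i, j in zip(*np.nonzero(keep))
    ]
    return edges


def edge_counts(edges: Iterable[CorrelationEdge]) -> dict[str, int]:
    """Total / positive / negative edge accounting."""
    pos = sum(1 for e in edges if e.sign == "positive")
    neg = sum(1 for e in edges if e.sign == "negative")
    return {"total": pos + neg, "positive": pos, "negative": neg}


def partners(
    edges: Iterable[CorrelationEdge],
    lnc_id: str,
    symbol_of: Mapping[str, str],
    known_lnc: Iterable[str],
) -> frozenset[str]:
    """Gene symbols of mRNAs sharing a retained edge (either sign) with lnc_id.

    ``known_lnc`` is the lncRNA universe the edges were built over, so an id
    outside it is rejected rather than silently yielding an empty set.
    """
    if lnc_id not in set(known_lnc):
        raise KeyError(f"unknown lncRNA id {lnc_id!r}")
    return frozenset(
        symbol_of[e.mrna_id] for e in edges if e.lnc_id == lnc_id and e.mrna_id in symbol_of
    )


def edges_to_table(edges: Sequence[CorrelationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lnc_id": [e.lnc_id for e in edges],
            "mrna_id": [e.mrna_id for e in edges],
            "r": [e.r for e in edges],
            "p_value": [e.p_value for e in edges],
            "sign": [e.sign for e in edges],
        }
    )


def edges_from_table(df: pd.DataFrame) -> list[CorrelationEdge]:
    return [
        CorrelationEdge(str(t.lnc_id), str(t.mrna_id), float(t.r), float(t.p_value), str(t.sign))
        for t in df.itertuples(index=False)
    ]
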