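"""Relative quantification by the 2^-ddCt method and array concordance.

Per sample, a target's cycle threshold is normalized to a reference gene
(GAPDH in the study): dCt = Ct(target) - Ct(reference).  Group dCt means
are contrasted, ddCt = dCt(case) - dCt(control), and the relative
expression level is 2^-ddCt — above 1 means up in the case group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from lncnet.diffexpr import DERecord

logger = logging.getLogger(__name__)

CT_COLUMNS = ["gene", "sample", "group", "Ct"]


@dataclass
class RelativeExpression:
    gene: str
    delta_ct_case: float
    delta_ct_control: float
    delta_delta_ct: float
    relative_level: float  # = 2 ** -delta_delta_ct


def validate_ct_table(t: pd.DataFrame, reference: Optional[str] = None) -> pd.DataFrame:
    if list(t.columns)[:4] != CT_COLUMNS:
        raise ValueError(f"Ct table columns must be {CT_COLUMNS}")
    if not (t["Ct"].astype(float) > 0).all():
        raise ValueError("Ct values must be positive cycle counts")
    bad = set(t["group"]) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown groups {sorted(bad)}")
    if reference is not None and reference not in set(t["gene"]):
        raise ValueError(f"reference gene {reference!r} absent from Ct table")
    return t


def read_ct_table(path) -> pd.DataFrame:
    return validate_ct_table(pd.read_csv(path, sep="\t"))


def delta_delta_ct(t: pd.DataFrame, reference: str, target: str) -> RelativeExpression:
    """2^-ddCt for one target against a reference gene.

    dCt is computed per sample and then averaged within each group, so a
    sample that lacks the reference measurement is simply dropped (with a
    warning) rather than poisoning a group mean.
    """
    if reference == target:
        raise ValueError("reference and target gene must differ")
    validate_ct_table(t, reference)
    ref = t[t["gene"] == reference].set_index("sample")["Ct"].astype(float)
    tgt = t[t["gene"] == target]
    if tgt.empty:
        raise ValueError(f"target gene {target!r} absent from Ct table")

    missing_ref = [s for s in tgt["sample"] if s not in ref.index]
    if missing_ref:
        logger.warning("dropping sample(s) without reference Ct: %s", missing_ref)
        tgt = tgt[~tgt["sample"].isin(missing_ref)]

    dct = tgt["Ct"].astype(float).to_numpy() - ref.loc[tgt["sample"]].to_numpy()
    by_group = pd.Series(dct, index=tgt["group"].to_numpy()).groupby(level=0).mean()
    for g in ("case", "control"):
        if g not in by_group.index:
            raise ValueError(f"no usable samples for group {g!r} and target {target!r}")
    ddct = float(by_group["case"] - by_group["control"])
    return RelativeExpression(
        gene=target,
        delta_ct_case=float(by_group["case"]),
        delta_ct_control=float(by_group["control"]),
        delta_delta_ct=ddct,
        relative_level=2.0 ** (-ddct),
    )


@dataclass
class ConcordanceReport:
    table: pd.DataFrame        # gene, ddCt, relative_level, microarray_direction, agree
    fraction_agree: float      # over determinate genes only
    n_determinate: int


def concordance(de: Sequence[DERecord], rel: Iterable[RelativeExpression]) -> ConcordanceReport:
    """Direction agreement between qPCR relative levels and array DE calls.

    A gene agrees when the array direction is up and 2^-ddCt > 1, or down
    and 2^-ddCt < 1.  A relative level of exactly 1 is indeterminate and is
    excluded from the summary fraction.
    """
    directions = {r.probe_id: r.direction for r in de}
    rows = []
    for r in rel:
        if r.gene not in directions:
            continue
        d = directions[r.gene]
        if r.relative_level == 1.0:
            agree: Optional[bool] = None
        else:
            agree = (d == "up") == (r.relative_level > 1.0)
        rows.append(
            {
                "gene": r.gene,
                "delta_delta_ct": r.delta_delta_ct,
                "relative_level": r.relative_level,
                "microarray_direction": d,
                "agree": agree,
            }
        )
    if not rows:
        raise ValueError("no genes shared between qPCR results and DE table")
    table = pd.DataFrame(rows)
    determinate = table["agree"].notna()
    n_det = int(determinate.sum())
    frac = float(table.loc[determinate, "agree"].mean()) if n_det else float("nan")
    return ConcordanceReport(table=table, fraction_agree=frac, n_determinate=n_det)
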