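"""Hypergeometric gene-set enrichment and lncRNA-TF association.

Function prediction by guilt-by-association: a lncRNA's coexpressed mRNA
set is tested for over-representation in each functional term (GO/KEGG
style) or TF target set with the hypergeometric upper tail —

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

where N is the background universe (annotated mRNA symbols on the array
by default), K the term size in the universe, n the query size and k the
overlap.  The tail is evaluated in exact big-integer arithmetic and
rounded once, so results are deterministic at every problem size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("GO_BP", "GO_CC", "GO_MF", "KEGG", "TF")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    category: str
    members: frozenset[str]

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be in {CATEGORIES}, got {self.category!r}")
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


@dataclass
class GeneSetDB:
    """An ordered collection of gene sets with unique ids (GMT-backed)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self):
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate set_id in gene-set database")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)

    def to_gmt(self, path) -> None:
        """Write standard GMT: name, description, then tab-separated symbols."""
        with open(path, "w") as fh:
            for s in self.sets:
                desc = f"{s.category}|{s.name}"
                fh.write("\t".join([s.set_id, desc] + sorted(s.members)) + "\n")

    @classmethod
    def from_gmt(cls, path, category: Optional[str] = None) -> "GeneSetDB":
        """Read GMT.  The description field may carry ``CATEGORY|name``; a
        bare description uses ``category`` (required in that case)."""
        sets = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                set_id, desc, members = parts[0], parts[1], parts[2:]
                if "|" in desc:
                    cat, name = desc.split("|", 1)
                else:
                    cat, name = category, desc
                if cat is None:
                    raise ValueError("GMT lacks category tags; pass category=...")
                sets.append(GeneSet(set_id, name, cat, frozenset(members)))
        return cls(sets)


@dataclass
class EnrichmentRecord:
    """Hypergeometric upper-tail result for one gene set against a query."""

    set_id: str
    category: str
    k: int  # overlap
    K: int  # set size in universe
    n: int  # query size in universe
    N: int  # universe size
    p_value: float
    q_value: Optional[float] = None


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exactly.

    The tail sum is accumulated as one big integer over C(N, n) and divided
    once; Python's correctly-rounded integer division makes the float result
    identical to rational-arithmetic enumeration.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    numerator = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return numerator / comb(N, n)


def _record_key(r: EnrichmentRecord):
    # ascending p, then larger overlap first, then set id: a total order
    return (r.p_value, -r.k, r.set_id)


def enrich(
    query: Iterable[str],
    db: GeneSetDB,
    universe: Iterable[str],
    bh: bool = False,
) -> list[EnrichmentRecord]:
    """Test a gene set against every db entry within a background universe.

    The query is silently restricted to the universe (dropped symbols are
    counted in a warning); db sets disjoint from the universe (K = 0) are
    omitted.  Records are ranked by ascending p with a deterministic
    tie-break, so the result is invariant to db and query ordering.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query)
    dropped = len(query - universe)
    if dropped:
        logger.warning("%d query symbol(s) outside the universe dropped", dropped)
    query &= universe
    if not query:
        raise ValueError("query empty after restriction to the universe")

    N, n = len(universe), len(query)
    records = []
    for s in db:
        members = s.members & universe
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        records.append(
            EnrichmentRecord(
                set_id=s.set_id, category=s.category,
                k=k, K=K, n=n, N=N,
                p_value=hypergeom_tail(k, K, n, N),
            )
        )
    records.sort(key=_record_key)
    if bh and records:
        m = len(records)
        # BH over the rank-sorted p-values
        adj = 1.0
        qs = [0.0] * m
        for i in range(m - 1, -1, -1):
            adj = min(adj, records[i].p_value * m / (i + 1))
            qs[i] = adj
        for rec, qv in zip(records, qs):
            rec.q_value = qv
    return records


def lnc_tf_pairs(
    lnc_ids: Sequence[str],
    partner_sets: Mapping[str, Iterable[str]],
    tf_db: GeneSetDB,
    universe: Iterable[str],
    top_k: int = 5,
) -> list[tuple[str, str, float]]:
    """Rank TFs per lncRNA by enrichment of its coexpression partner set.

    For each lncRNA the TF target sets are scored with ``enrich`` and the
    ``top_k`` lowest-p TFs with nonzero overlap are retained (fewer when
    fewer overlap).  A lncRNA with an empty partner set yields no pairs.
    """
    if top_k < 0:
        raise ValueError("top_k must be non-negative")
    universe = frozenset(universe)
    pairs: list[tuple[str, str, float]] = []
    for lnc in lnc_ids:
        ps = frozenset(partner_sets.get(lnc, ())) & universe
        if not ps:
            logger.warning("lncRNA %s has no usable coexpression partners", lnc)
            continue
        recs = [r for r in enrich(ps, tf_db, universe) if r.k > 0]
        pairs.extend((lnc, r.set_id, r.p_value) for r in recs[:top_k])
    return pairs


def enrichment_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "set_id": [r.set_id for r in records],
            "category": [r.category for r in records],
            "k": [r.k for r in records],
            "K": [r.K for r in records],
            "n": [r.n for r in records],
            "N": [r.N for r in records],
            "p_value": [r.p_value for r in records],
        }
    )
    if records and records[0].q_value is not None:
        df["q_value"] = [r.q_value for r in records]
    return df
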