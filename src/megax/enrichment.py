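"""Over-representation analysis of gene lists against gene-set collections.

For a query of n genes drawn from a universe of N genes, a set with K
universe members and k overlapping genes is scored with the hypergeometric
upper tail P[X >= k].  Benjamini–Hochberg q-values are computed across all
tested sets and the Jaccard similarity |query ∩ set| / |query ∪ set| is
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import GeneSet


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    set_id: str
    overlap: int
    set_size: int
    p_value: float
    q_value: float
    jaccard: float


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def enrich(
    query: Iterable[str],
    collections: Sequence[GeneSet],
    universe: Iterable[str] | None = None,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of *query* in each gene set.

    The universe defaults to the union of all collection members; every set
    is intersected with the universe before testing and the query must be a
    subset of the universe.  Rows come back sorted by ascending p, ties by
    set name; q-values are BH across all tested sets.
    """
    query_set = set(query)
    if not query_set:
        raise ValidationError("query gene list is empty")
    if universe is None:
        uni = set().union(*(s.members for s in collections)) if collections else set()
    else:
        uni = set(universe)
    if not uni:
        raise ValidationError("universe is empty")
    extra = query_set - uni
    if extra:
        raise ValidationError(
            "query genes missing from universe: " + ", ".join(sorted(extra))
        )
    N, n = len(uni), len(query_set)
    rows = []
    for s in collections:
        members = s.members & uni
        if not members:
            continue
        k = len(query_set & members)
        p = hypergeom_tail(k, N, len(members), n)
        jac = len(query_set & s.members) / len(query_set | s.members)
        rows.append((s.name, s.external_id, k, len(members), p, jac))
    q = bh_fdr([r[4] for r in rows])
    out = [
        EnrichmentRow(
            set_name=name, set_id=sid, overlap=k, set_size=K,
            p_value=p, q_value=qv, jaccard=jac,
        )
        for (name, sid, k, K, p, jac), qv in zip(rows, q)
    ]
    out.sort(key=lambda r: (r.p_value, r.set_name))
    return out


def enrichment_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Tidy table of enrichment rows (one line per gene set)."""
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in rows],
            "set_id": [r.set_id for r in rows],
            "overlap": [r.overlap for r in rows],
            "set_size": [r.set_size for r in rows],
            "p_value": [r.p_value for r in rows],
            "q_value": [r.q_value for r in rows],
            "jaccard": [r.jaccard for r in rows],
        }
    )
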