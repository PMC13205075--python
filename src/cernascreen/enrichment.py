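"""Hypergeometric over-representation analysis with gene-ratio ranking.

For a selected gene set of size n drawn from a universe of size N, a term
with K in-universe members and overlap k is scored by the hypergeometric
upper tail P(X >= k). Reporting ranks terms by gene ratio k/n (the
fraction of the selected set annotated to the term), the convention used
for top-10 GO terms per category and top-20 pathways.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import ConsistencyError, FormatError
from .types import EnrichmentRecord, TermAnnotation

#: default per-namespace report sizes: top 10 GO terms per category,
#: top 20 pathways
DEFAULT_TOP_LIMITS = {"BP": 10, "MF": 10, "CC": 10, "pathway": 20}


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed stably.

    N = universe size, K = annotated in universe, n = selected, k = overlap.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if not isinstance(v, (int,)) or isinstance(v, bool):
            raise FormatError(f"{name} must be an integer, got {v!r}")
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise FormatError(
            f"invalid hypergeometric parameters N={N}, K={K}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    selected: Iterable[str],
    terms: Sequence[TermAnnotation],
    universe: Iterable[str],
    direction_label: str = "",
) -> list[EnrichmentRecord]:
    """Over-representation of ``selected`` within ``universe`` for each term.

    Term memberships are intersected with the universe; terms with zero
    overlap (k = 0) are dropped before BH adjustment (they carry p = 1 and
    only dilute). BH is applied within each namespace. Output order is
    (namespace, p, term_id). ``direction_label`` is carried for reporting
    convenience only (e.g. "up"/"down").
    """
    universe = set(universe)
    if not universe:
        raise ConsistencyError("empty universe")
    selected = set(selected)
    if not selected <= universe:
        extra = sorted(selected - universe)
        raise ConsistencyError(f"selected features outside the universe: {extra[:5]}")
    N = len(universe)
    n = len(selected)
    records: list[EnrichmentRecord] = []
    for t in terms:
        members = t.members & universe
        K = len(members)
        k = len(members & selected)
        if k == 0:
            continue
        records.append(
            EnrichmentRecord(
                term_id=t.term_id,
                namespace=t.namespace,
                k=k,
                n=n,
                K=K,
                N=N,
                gene_ratio=k / n if n else 0.0,
                p=hypergeom_upper(N, K, n, k),
            )
        )
    # BH within namespace
    by_ns: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_ns.setdefault(r.namespace, []).append(i)
    adjusted: dict[int, float] = {}
    for ns, idx in by_ns.items():
        adj = bh_adjust([records[i].p for i in idx])
        for i, a in zip(idx, adj):
            adjusted[i] = float(a)
    records = [
        EnrichmentRecord(
            term_id=r.term_id, namespace=r.namespace, k=r.k, n=r.n, K=r.K, N=r.N,
            gene_ratio=r.gene_ratio, p=r.p, p_adj=adjusted[i],
        )
        for i, r in enumerate(records)
    ]
    return sorted(records, key=lambda r: (r.namespace, r.p, r.term_id))


def top_terms(
    records: Sequence[EnrichmentRecord],
    limits: Mapping[str, int] = DEFAULT_TOP_LIMITS,
) -> list[EnrichmentRecord]:
    """Within each namespace, the top terms by gene ratio.

    Sort key: gene_ratio descending, ties broken by ascending p then
    term_id; truncated to the namespace's limit (namespaces without a limit
    are kept whole).
    """
    out: list[EnrichmentRecord] = []
    namespaces = []
    for r in records:
        if r.namespace not in namespaces:
            namespaces.append(r.namespace)
    for ns in namespaces:
        ns_records = [r for r in records if r.namespace == ns]
        ns_records.sort(key=lambda r: (-r.gene_ratio, r.p, r.term_id))
        limit = limits.get(ns)
        out.extend(ns_records if limit is None else ns_records[:limit])
    return out


def enrichment_table(records: Sequence[EnrichmentRecord], direction: str = "") -> pd.DataFrame:
    """Tabulate enrichment records for TSV export."""
    df = pd.DataFrame(
        {
            "term_id": [r.term_id for r in records],
            "namespace": [r.namespace for r in records],
            "k": [r.k for r in records],
            "n": [r.n for r in records],
            "K": [r.K for r in records],
            "N": [r.N for r in records],
            "gene_ratio": [r.gene_ratio for r in records],
            "p": [r.p for r in records],
            "p_adj": [r.p_adj for r in records],
        }
    )
    if direction:
        df.insert(0, "direction", direction)
    return df
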