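"""Gene-set over-representation analysis.

A target gene set is tested against every term of one annotation catalog
with a one-sided hypergeometric upper-tail test, followed by
Benjamini-Hochberg step-up adjustment across all terms of that one
catalog. A term is called significant when its adjusted p-value is below
the threshold (default 0.05).

The background universe is the catalog's own gene universe (the union of
its term gene sets); target genes absent from the background are dropped
before testing and their count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import DomainError
from .io import AnnotationCatalog

__all__ = [
    "EnrichmentRecord",
    "EnrichmentTable",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
]

DEFAULT_ALPHA = 0.05

ENRICHMENT_COLUMNS = [
    "term_id",
    "description",
    "k",
    "K",
    "n",
    "N",
    "p_raw",
    "p_adj",
    "significant",
]


def hypergeom_upper_tail(
    k_overlap: int, K_term: int, n_targets: int, N_background: int
) -> float:
    """P(X >= k_overlap) for X ~ Hypergeometric(N_background, K_term, n_targets).

    X counts how many of ``n_targets`` genes drawn without replacement
    from a background of ``N_background`` genes fall in a term of size
    ``K_term``. Computed via the survival function (log-gamma based), not
    naive factorials.
    """
    if not (0 <= K_term <= N_background):
        raise DomainError(f"need 0 <= K_term <= N_background, got K={K_term}, N={N_background}")
    if not (0 <= n_targets <= N_background):
        raise DomainError(f"need 0 <= n_targets <= N_background, got n={n_targets}, N={N_background}")
    lo = max(0, n_targets + K_term - N_background)
    hi = min(K_term, n_targets)
    if not (lo <= k_overlap <= hi):
        raise DomainError(
            f"k_overlap={k_overlap} outside feasible range [{lo}, {hi}] "
            f"for K={K_term}, n={n_targets}, N={N_background}"
        )
    # sf(k-1) = P(X >= k); exact 1.0 at the lower support bound
    if k_overlap <= lo:
        return 1.0
    return float(hypergeom.sf(k_overlap - 1, N_background, K_term, n_targets))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    With order statistics p_(1) <= ... <= p_(m), the adjusted value at
    rank i is min_{j >= i} (p_(j) * m / j), capped at 1, mapped back to
    the input order. Output has the same length and order as the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DomainError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1, dtype=float)
    scaled = p[order] * m / ranks
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted_sorted
    return out


@dataclass(frozen=True)
class EnrichmentRecord:
    """Hypergeometric test result for one catalog term."""

    term_id: str
    description: str
    k_overlap: int
    K_term: int
    n_targets: int
    N_background: int
    p_raw: float
    p_adj: float
    significant: bool


@dataclass
class EnrichmentTable:
    """All per-term results for one (gene set, namespace) pair.

    ``label`` identifies the tested gene set (a chemical_id, or "union"
    for the pooled mixture target set). Records are sorted by
    (p_adj ascending, term_id ascending) so output order is deterministic.
    """

    label: str
    namespace: str
    records: list[EnrichmentRecord] = field(default_factory=list)
    n_dropped: int = 0
    alpha: float = DEFAULT_ALPHA

    @property
    def no_testable_genes(self) -> bool:
        return not self.records

    def significant_terms(self) -> set[str]:
        return {r.term_id for r in self.records if r.significant}

    def record_for(self, term_id: str) -> EnrichmentRecord:
        for rec in self.records:
            if rec.term_id == term_id:
                return rec
        raise KeyError(term_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    r.term_id,
                    r.description,
                    r.k_overlap,
                    r.K_term,
                    r.n_targets,
                    r.N_background,
                    r.p_raw,
                    r.p_adj,
                    r.significant,
                )
                for r in self.records
            ],
            columns=ENRICHMENT_COLUMNS,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    def __len__(self) -> int:
        return len(self.records)


def enrich(
    target_genes: Iterable[str],
    catalog: AnnotationCatalog,
    alpha: float = DEFAULT_ALPHA,
    label: str = "",
) -> EnrichmentTable:
    """Test a gene set against every term of one catalog.

    Genes absent from the catalog background are dropped (count reported
    in ``n_dropped``). An empty effective target set yields an
    empty-records table rather than an exception. BH adjustment runs
    across all terms of this one catalog.
    """
    targets = set(target_genes)
    background = catalog.background
    effective = targets & background
    n_dropped = len(targets) - len(effective)
    if not effective:
        return EnrichmentTable(
            label=label, namespace=catalog.namespace, records=[],
            n_dropped=n_dropped, alpha=alpha,
        )
    n = len(effective)
    N = len(background)
    term_ids = sorted(catalog.terms)
    raw = np.empty(len(term_ids), dtype=float)
    overlaps: list[tuple[int, int]] = []
    for i, term_id in enumerate(term_ids):
        genes = catalog.genes(term_id)
        k = len(effective & genes)
        K = len(genes)
        raw[i] = hypergeom_upper_tail(k, K, n, N)
        overlaps.append((k, K))
    adjusted = bh_adjust(raw)
    records = [
        EnrichmentRecord(
            term_id=term_id,
            description=catalog.description(term_id),
            k_overlap=k,
            K_term=K,
            n_targets=n,
            N_background=N,
            p_raw=float(raw[i]),
            p_adj=float(adjusted[i]),
            significant=bool(adjusted[i] < alpha),
        )
        for i, (term_id, (k, K)) in enumerate(zip(term_ids, overlaps))
    ]
    records.sort(key=lambda r: (r.p_adj, r.term_id))
    return EnrichmentTable(
        label=label, namespace=catalog.namespace, records=records,
        n_dropped=n_dropped, alpha=alpha,
    )
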