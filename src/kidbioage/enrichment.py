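"""Gene-set over-representation analysis (hypergeometric ORA).

The universe (all measured, annotated genes) is explicit and mandatory:
query and set genes outside it are dropped (and counted) before testing.
The test is one-sided upper-tail: p = P(X ≥ k) for
X ~ Hypergeometric(N, K, n). A set is flagged significant when its BH
q-value within the collection is < 0.05 **and** the overlap has ≥ 3 genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSet:
    name: str
    genes: frozenset[str]
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise EnrichmentError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))


@dataclass
class ORAResult:
    set_name: str
    k: int  # overlap
    K: int  # set size within the universe
    n: int  # query size within the universe
    N: int  # universe size
    p: float
    overlap_genes: list[str] = field(default_factory=list)
    q: float | None = None
    significant: bool | None = None


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (tab-separated: name, description, genes…)."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise EnrichmentError(f"malformed GMT line {lineno}: expected name, description and >=1 gene")
        name, source, *genes = parts
        genes = [g for g in genes if g]
        if not genes:
            raise EnrichmentError(f"malformed GMT line {lineno}: no genes listed for set {name!r}")
        sets.append(GeneSet(name=name, genes=frozenset(genes), source=source or None))
    return sets


def _normalize(genes) -> frozenset[str]:
    if isinstance(genes, GeneSet):
        return genes.genes
    return frozenset(str(g).upper() for g in genes)


def hypergeom_overlap(query, reference, universe) -> ORAResult:
    """Exact upper-tail overlap test of ``query`` against ``reference``.

    Genes outside the universe are dropped (counts logged). With an empty
    reference the overlap is certain to be 0 and p = 1.
    """
    uni = _normalize(universe)
    if not uni:
        raise EnrichmentError("empty universe")
    q_raw, r_raw = _normalize(query), _normalize(reference)
    q, r = q_raw & uni, r_raw & uni
    dropped = len(q_raw - uni) + len(r_raw - uni)
    if dropped:
        logger.info("dropped %d genes outside the universe", dropped)
    if not q:
        raise EnrichmentError("query is empty after intersecting with the universe")
    overlap = sorted(q & r)
    k, K, n, N = len(overlap), len(r), len(q), len(uni)
    p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
    name = reference.name if isinstance(reference, GeneSet) else "reference"
    return ORAResult(set_name=name, k=k, K=K, n=n, N=N, p=min(p, 1.0), overlap_genes=overlap)


def ora_collection(query, collection: list[GeneSet], universe) -> list[ORAResult]:
    """One overlap test per set, BH-corrected within the collection.

    Significance flag: q < 0.05 and overlap ≥ 3 genes. Sorted by p.
    """
    if not collection:
        raise EnrichmentError("empty gene-set collection")
    results = [hypergeom_overlap(query, gs, universe) for gs in collection]
    for res, gs in zip(results, collection):
        res.set_name = gs.name
    qs = multipletests([r.p for r in results], method="fdr_bh")[1]
    for res, qv in zip(results, qs):
        res.q = float(qv)
        res.significant = bool(qv < 0.05 and res.k >= 3)
    return sorted(results, key=lambda r: r.p)


def ora_table(results: list[ORAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "overlap_k": [r.k for r in results],
            "set_size_K": [r.K for r in results],
            "query_size_n": [r.n for r in results],
            "universe_N": [r.N for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "significant": [r.significant for r in results],
            "overlap_genes": ["|".join(r.overlap_genes) for r in results],
        }
    )
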