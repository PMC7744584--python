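"""Disease-pathway mapping by hypergeometric enrichment.

For each disease the associated gene set is tested against every pathway in
a GMT collection with a two-sided hypergeometric enrichment/depletion test.
With ``X ~ Hypergeometric(N, K, n)`` — a universe of N annotated genes of
which K lie in the pathway, and n disease genes drawn from the universe —
the enrichment tail is ``p_e = P(X >= k)`` and the depletion tail
``p_d = P(X <= k)`` for the observed overlap k; the reported two-sided p is
the doubled smaller tail, capped at 1 (a minimum-likelihood variant is
available via ``method="minlike"``).  Per disease, p-values are
Bonferroni-adjusted across the pathway family (``adj_p = min(1, p*m)`` with
m the number of pathways).

The disease-pathway network links a disease to a pathway only when the
disease's genes are significantly *enriched* in that pathway after
adjustment (``adj_p <= alpha``); depleted records never form edges.

The default universe is the union of the pathway gene sets (the annotated
universe conditioning of the classic hyperGTest idiom); pass an explicit
``universe`` to widen it to all integrated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .integrate import Category

logger = logging.getLogger("diseasome")

__all__ = [
    "Direction",
    "PathwayCollection",
    "EnrichmentRecord",
    "read_gmt",
    "hypergeom_two_sided",
    "hypergeom_two_sided_many",
    "enrich_disease",
    "enrich_table",
    "build_disease_pathway_network",
    "shared_pathway_pairs",
    "write_records",
]


class Direction(str, Enum):
    ENRICHED = "ENRICHED"
    DEPLETED = "DEPLETED"

    def __str__(self) -> str:
        return self.value


@dataclass
class PathwayCollection:
    """Gene sets keyed by pathway id, plus their union (the universe)."""

    pathways: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]
    skipped_lines: int = 0

    def __len__(self) -> int:
        return len(self.pathways)


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read pathway gene sets in GMT format.

    One pathway per line: ``name<TAB>description<TAB>gene1<TAB>gene2…``.
    Duplicate genes within a line collapse to a set; lines with fewer than
    three fields are skipped and counted.
    """
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    skipped = 0
    with open(path, newline="") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                if line.strip():
                    skipped += 1
                continue
            pid, description = fields[0].strip(), fields[1].strip()
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                skipped += 1
                continue
            pathways[pid] = (description, genes)
    universe = frozenset().union(*(g for _, g in pathways.values())) if pathways \
        else frozenset()
    return PathwayCollection(pathways, universe, skipped)


# ---------------------------------------------------------------------------
# The test
# ---------------------------------------------------------------------------

def _validate(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (max(0, n + K - N) <= k <= min(K, n)):
        raise ValueError(
            f"k={k} outside hypergeometric support "
            f"[{max(0, n + K - N)}, {min(K, n)}] for K={K}, n={n}, N={N}"
        )


def hypergeom_two_sided_many(ks, Ks, ns, Ns):
    """Vectorized doubled-tail two-sided test.

    Broadcasts over the four count arrays and returns ``(p, enriched)``
    where ``enriched`` is a boolean array (True where the enrichment tail
    is the smaller, ties included).
    """
    ks, Ks, ns, Ns = np.broadcast_arrays(
        np.asarray(ks), np.asarray(Ks), np.asarray(ns), np.asarray(Ns)
    )
    p_e = hypergeom.sf(ks - 1, Ns, Ks, ns)
    p_d = hypergeom.cdf(ks, Ns, Ks, ns)
    p = np.minimum(1.0, 2.0 * np.minimum(p_e, p_d))
    return p, p_e <= p_d


def hypergeom_two_sided(
    k: int, K: int, n: int, N: int, method: str = "doubled"
) -> tuple[float, Direction]:
    """Two-sided hypergeometric enrichment/depletion test.

    Returns ``(p, direction)`` where direction is the smaller tail
    (ENRICHED when ``P(X >= k) <= P(X <= k)``; exact ties count as
    enriched).  ``method="doubled"`` doubles the smaller tail and caps at 1;
    ``method="minlike"`` sums the probabilities of all outcomes no more
    likely than k.  Tail probabilities come from scipy's hypergeometric
    distribution, which works on log-probabilities internally.
    """
    _validate(k, K, n, N)
    p_e = float(hypergeom.sf(k - 1, N, K, n))
    p_d = float(hypergeom.cdf(k, N, K, n))
    direction = Direction.ENRICHED if p_e <= p_d else Direction.DEPLETED
    if method == "doubled":
        p = min(1.0, 2.0 * min(p_e, p_d))
    elif method == "minlike":
        lo, hi = max(0, n + K - N), min(K, n)
        support = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(support, N, K, n)
        p_k = float(hypergeom.pmf(k, N, K, n))
        # tolerance absorbs float noise when comparing equal likelihoods
        p = float(pmf[pmf <= p_k * (1 + 1e-7)].sum())
        p = min(1.0, p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return p, direction


@dataclass(frozen=True)
class EnrichmentRecord:
    """One (disease, pathway) test: counts, raw and adjusted p, direction."""

    disease_id: str
    pathway_id: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    adj_p: float
    direction: Direction
    m_tests: int


def enrich_disease(
    disease_genes: Iterable[str],
    coll: PathwayCollection,
    disease_id: str = "",
    universe: frozenset[str] | None = None,
    method: str = "doubled",
) -> list[EnrichmentRecord]:
    """Test one disease's gene set against every pathway in the collection.

    ``n`` counts only disease genes inside the universe; a disease with no
    gene in the universe is untestable and yields an empty list.  The
    Bonferroni family is the pathway collection (m = number of pathways),
    applied per disease.
    """
    uni = coll.universe if universe is None else universe
    genes = set(disease_genes) & uni
    n, N, m = len(genes), len(uni), len(coll.pathways)
    if n == 0 or m == 0:
        return []

    pids = sorted(coll.pathways)
    ks = np.array([len(genes & coll.pathways[p][1]) for p in pids])
    Ks = np.array([len(coll.pathways[p][1] & uni) for p in pids])
    if method == "doubled":
        ps, enriched = hypergeom_two_sided_many(ks, Ks, n, N)
        dirs = [Direction.ENRICHED if e else Direction.DEPLETED for e in enriched]
    else:
        ps_dirs = [hypergeom_two_sided(int(k), int(K), n, N, method=method)
                   for k, K in zip(ks, Ks)]
        ps = np.array([p for p, _ in ps_dirs])
        dirs = [d for _, d in ps_dirs]

    return [
        EnrichmentRecord(
            disease_id=disease_id,
            pathway_id=pid,
            k=int(k),
            K=int(K),
            n=n,
            N=N,
            p_value=float(p),
            adj_p=min(1.0, float(p) * m),
            direction=direction,
            m_tests=m,
        )
        for pid, k, K, p, direction in zip(pids, ks, Ks, ps, dirs)
    ]


def enrich_table(
    disease_genes: Mapping[str, set[str]],
    coll: PathwayCollection,
    universe: frozenset[str] | None = None,
    method: str = "doubled",
) -> list[EnrichmentRecord]:
    """Run :func:`enrich_disease` for every disease, in sorted-id order."""
    records: list[EnrichmentRecord] = []
    for did in sorted(disease_genes):
        records.extend(
            enrich_disease(disease_genes[did], coll, disease_id=did,
                           universe=universe, method=method)
        )
    return records


# ---------------------------------------------------------------------------
# Disease-pathway network
# ---------------------------------------------------------------------------

def build_disease_pathway_network(
    records: Sequence[EnrichmentRecord],
    alpha: float = 0.05,
    categories: Mapping[str, Category] | None = None,
) -> nx.Graph:
    """Link diseases to pathways they are significantly enriched in.

    An edge requires ``direction == ENRICHED`` and ``adj_p <= alpha``;
    depleted records never produce edges.  Only endpoints of surviving
    edges enter the graph.  ``categories`` (disease_id -> OD/CD/BOTH) is
    attached to disease nodes for downstream OD/CD pairing.
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    categories = categories or {}
    g = nx.Graph()
    for rec in records:
        if rec.direction is not Direction.ENRICHED or rec.adj_p > alpha:
            continue
        cat = categories.get(rec.disease_id)
        g.add_node(rec.disease_id, kind="disease",
                   category=cat.value if cat else "")
        g.add_node(rec.pathway_id, kind="pathway")
        g.add_edge(rec.disease_id, rec.pathway_id,
                   adj_p=rec.adj_p, p_value=rec.p_value, weight=rec.k)
    return g


def shared_pathway_pairs(g: nx.Graph) -> list[tuple[str, str, str]]:
    """All (OD, CD, pathway) triples joined through one enriched pathway.

    A disease labeled BOTH can stand on either side of the pair; a disease
    is never paired with itself.  Output is sorted by pathway id, then OD
    id, then CD id.
    """
    triples: list[tuple[str, str, str]] = []
    pathways = sorted(v for v, d in g.nodes(data=True) if d.get("kind") == "pathway")
    for pw in pathways:
        diseases = [(v, g.nodes[v].get("category")) for v in g[pw]]
        ods = sorted(v for v, c in diseases if c in ("OD", "BOTH"))
        cds = sorted(v for v, c in diseases if c in ("CD", "BOTH"))
        for od in ods:
            for cd in cds:
                if od != cd:
                    triples.append((od, cd, pw))
    return triples


def write_records(records: Sequence[EnrichmentRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("disease_id\tpathway_id\tk\tK\tn\tN\tp_value\tadj_p"
                 "\tdirection\tm_tests\n")
        for r in records:
            fh.write(
                f"{r.disease_id}\t{r.pathway_id}\t{r.k}\t{r.K}\t{r.n}\t{r.N}"
                f"\t{r.p_value:.6g}\t{r.adj_p:.6g}\t{r.direction}\t{r.m_tests}\n"
            )
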