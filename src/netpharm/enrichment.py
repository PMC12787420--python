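"""Gene-set over-representation analysis against GMT libraries.

One-sided hypergeometric (Fisher's exact) upper-tail test per term,
Benjamini–Hochberg FDR across the library, ranking by raw p-value with
deterministic tie-breaks (larger overlap first, then term id).  The
background universe defaults to the union of the library's genes and is
explicitly configurable, since over-representation p-values are defined
only relative to a stated background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .ingest import GeneSet, normalize_symbol


@dataclass
class AnnotationLibrary:
    """A named collection of gene-set terms with a background universe."""

    name: str
    terms: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.terms.values()) if self.terms else set()
        for term_id, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term_id!r} has no genes")
            if not genes <= self.universe:
                raise ValueError(f"term {term_id!r} has genes outside the universe")


@dataclass(frozen=True)
class EnrichmentTerm:
    """One tested term: overlap k of a size-n query with a size-K term
    in a size-N universe, with raw p and BH-adjusted FDR."""

    term_id: str
    library: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    fdr: float


def read_gmt(path: str | Path, name: Optional[str] = None, universe: Optional[set[str]] = None) -> AnnotationLibrary:
    """Read a GMT file (term, description, tab-separated genes).

    Lines with fewer than three fields are rejected with their line
    number.  Unless overridden, the universe is the union of all term
    genes.
    """
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(fields)}")
            term_id = fields[0].strip()
            descriptions[term_id] = fields[1].strip()
            genes = {normalize_symbol(g) for g in fields[2:] if g.strip()}
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term_id!r} has no genes")
            terms[term_id] = genes
    lib_name = name if name is not None else Path(path).stem
    return AnnotationLibrary(name=lib_name, terms=terms, universe=universe or set(), descriptions=descriptions)


def write_gmt(library: AnnotationLibrary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id in sorted(library.terms):
            desc = library.descriptions.get(term_id, "na")
            genes = "\t".join(sorted(library.terms[term_id]))
            fh.write(f"{term_id}\t{desc}\t{genes}\n")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N, K, n): the Fisher one-sided p."""
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_enrich(query: GeneSet | set[str], library: AnnotationLibrary) -> list[EnrichmentTerm]:
    """Test every library term for over-representation of the query.

    Query genes outside the universe are dropped with a warning.  The
    returned list carries both raw p-values and BH-adjusted FDR, sorted
    ascending by p with ties broken by larger overlap then term id.
    """
    genes = query.genes if isinstance(query, GeneSet) else set(query)
    N = len(library.universe)
    if N == 0:
        raise ValueError("library has an empty universe")
    outside = genes - library.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the {library.name} universe dropped",
            stacklevel=2,
        )
    in_universe = genes & library.universe
    n = len(in_universe)
    term_ids = sorted(library.terms)
    raw = []
    for term_id in term_ids:
        term_genes = library.terms[term_id]
        k = len(in_universe & term_genes)
        raw.append((term_id, k, len(term_genes), hypergeom_upper_tail(k, len(term_genes), n, N)))
    fdrs = bh_adjust([p for _, _, _, p in raw])
    results = [
        EnrichmentTerm(
            term_id=term_id, library=library.name, k=k, K=K, n=n, N=N,
            p_value=p, fdr=float(fdr),
        )
        for (term_id, k, K, p), fdr in zip(raw, fdrs)
    ]
    results.sort(key=lambda t: (t.p_value, -t.k, t.term_id))
    return results


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        return ps
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(ps, method="fdr_bh")[1]


def top_k(terms: Iterable[EnrichmentTerm], k: int, category: Optional[str] = None) -> list[EnrichmentTerm]:
    """Top-``k`` terms by ascending p (ties: larger overlap, then term id)."""
    if k <= 0:
        raise ValueError("k must be positive")
    pool = [t for t in terms if category is None or t.library == category]
    pool.sort(key=lambda t: (t.p_value, -t.k, t.term_id))
    return pool[:k]


def write_enrichment_table(terms: Iterable[EnrichmentTerm], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tlibrary\tk\tK\tn\tN\tp_value\tfdr\n")
        for t in terms:
            fh.write(
                f"{t.term_id}\t{t.library}\t{t.k}\t{t.K}\t{t.n}\t{t.N}\t"
                f"{t.p_value:.6g}\t{t.fdr:.6g}\n"
            )
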