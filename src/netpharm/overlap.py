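"""Intersection of predicted drug targets with a disease gene set.

The overlap itself is plain set intersection on normalised symbols; an
optional hypergeometric upper-tail test quantifies whether the overlap
exceeds chance for a stated background universe.  The universe is never
implicit — it must be supplied (or taken from a PPI network's node set by
the caller) because gene-list overlap p-values are meaningless without a
declared background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy.stats import hypergeom

from .ingest import GeneSet


@dataclass
class OverlapSummary:
    """Venn-style counts for a target set vs a disease gene set."""

    n_targets: int
    n_disease: int
    n_shared: int
    universe_size: Optional[int] = None
    hypergeometric_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_targets, self.n_disease):
            raise ValueError("n_shared exceeds one of the input set sizes")
        if min(self.n_targets, self.n_disease, self.n_shared) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_target_only(self) -> int:
        return self.n_targets - self.n_shared

    @property
    def n_disease_only(self) -> int:
        return self.n_disease - self.n_shared


def intersect(targets: GeneSet, disease: GeneSet) -> GeneSet:
    """Exact intersection of two normalised gene sets (label ``shared``)."""
    return GeneSet(label="shared", genes=targets.genes & disease.genes)


def overlap_significance(summary: OverlapSummary, universe_size: int) -> float:
    """Upper-tail P[X >= n_shared] for X ~ Hypergeom(N, K=n_disease, n=n_targets).

    The null model draws ``n_targets`` genes uniformly without replacement
    from a universe of ``universe_size`` genes of which ``n_disease`` are
    disease-associated.
    """
    n, K, k = summary.n_targets, summary.n_disease, summary.n_shared
    if universe_size < summary.n_targets + summary.n_disease_only:
        raise ValueError(
            f"universe_size {universe_size} cannot hold {n} targets plus "
            f"{summary.n_disease_only} disease-only genes"
        )
    if universe_size < K:
        raise ValueError("universe_size smaller than the disease set")
    # sf(k-1) = P[X >= k]; scipy's hypergeom is exact at these scales
    return float(hypergeom.sf(k - 1, universe_size, K, n))


def summarize_overlap(
    targets: GeneSet, disease: GeneSet, universe_size: Optional[int] = None
) -> OverlapSummary:
    """Compute Venn counts and, when a universe is given, the tail p-value."""
    shared = intersect(targets, disease)
    summary = OverlapSummary(
        n_targets=len(targets), n_disease=len(disease), n_shared=len(shared)
    )
    if universe_size is not None:
        summary.universe_size = universe_size
        summary.hypergeometric_p = overlap_significance(summary, universe_size)
    return summary
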