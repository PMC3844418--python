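"""Common Pathway Scanning (CPS): pathway/complex association statistics.

Candidates are predicted because they share a pathway (or complex) with a
known disease gene (seeded mode) or because a pathway recurs across several
phenotype-associated loci (ab initio mode). Pathway association is scored
with a one-sided (over-representation) Fisher's exact test on the partition
of the gene universe into search-space vs non-space genes; the default
significance threshold is p < 0.05 on the raw p-value. Direct
protein-interaction neighborhood evidence is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma, log
from typing import Optional, Sequence

from .bundle import ReferenceBundle
from .loci import SearchSpace
from .models import (
    STAT_COUNT,
    STAT_P,
    STAT_SCORE,
    CandidatePrediction,
    GeneSet,
)

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_LOCI = 2

PPIN = "PPIN"


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 margin counts for one pathway vs one search space.

    k = space genes in the pathway, n = distinct space genes,
    K = pathway genes in the universe, N = universe size.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"require 0 <= k <= min(n, K): {self}")
        if not (self.n <= self.N and self.K <= self.N):
            raise ValueError(f"require n <= N and K <= N: {self}")


@dataclass
class PathwayAssociation:
    """One pathway's association with the search space."""

    set_id: str
    source_db: str
    name: str
    p_value: float
    counts: ContingencyCounts
    overlap_genes: tuple[str, ...]
    seed_members: tuple[str, ...] = ()
    loci_hit: int = 0
    retained: bool = False


def _lchoose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return float("-inf")
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact_greater(counts: ContingencyCounts) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k | N, K, n).

    Computed in log space (log-binomials via lgamma, stabilized tail sum),
    so tiny tails keep full relative precision. Returns a value in (0, 1].
    """
    k, n, K, N = counts.k, counts.n, counts.K, counts.N
    lo = max(0, n + K - N)
    hi = min(n, K)
    if k <= lo:
        return 1.0
    denom = _lchoose(N, n)
    terms = [
        _lchoose(K, x) + _lchoose(N - K, n - x) - denom for x in range(k, hi + 1)
    ]
    m = max(terms)
    p = exp(m + log(sum(exp(t - m) for t in terms)))
    return min(1.0, p)


def _space_overlap(
    gs: GeneSet, space: SearchSpace, universe: set[str]
) -> tuple[tuple[str, ...], int]:
    overlap = tuple(sorted(gs.members & space.genes & universe))
    loci = set()
    for gid in overlap:
        loci |= space.loci_of(gid)
    return overlap, len(loci)


def _associate(
    gs: GeneSet,
    space: SearchSpace,
    universe: set[str],
    n: int,
    seeds: frozenset[str],
) -> Optional[PathwayAssociation]:
    overlap, loci_hit = _space_overlap(gs, space, universe)
    if not overlap:
        return None
    counts = ContingencyCounts(
        k=len(overlap), n=n, K=len(gs.members & universe), N=len(universe)
    )
    return PathwayAssociation(
        set_id=gs.set_id,
        source_db=gs.source_db,
        name=gs.name,
        p_value=fisher_exact_greater(counts),
        counts=counts,
        overlap_genes=overlap,
        seed_members=tuple(sorted(gs.members & seeds)),
        loci_hit=loci_hit,
    )


def _pathway_predictions(
    associations: Sequence[PathwayAssociation],
    space: SearchSpace,
    bundle: ReferenceBundle,
    method: str,
    exclude: frozenset[str],
) -> list[CandidatePrediction]:
    """Each space gene in a retained pathway, scored by the lowest p-value of
    the retained pathways it belongs to (ties: lexicographic set_id)."""
    retained = [a for a in associations if a.retained]
    best: dict[str, PathwayAssociation] = {}
    for assoc in sorted(retained, key=lambda a: (a.p_value, a.source_db, a.set_id)):
        for gid in assoc.overlap_genes:
            if gid not in exclude:
                best.setdefault(gid, assoc)
    preds = []
    for gid in sorted(best):
        assoc = best[gid]
        preds.append(
            CandidatePrediction(
                gene_id=gid,
                symbol=bundle.genes[gid].symbol,
                locus_ids=tuple(sorted(space.loci_of(gid))),
                method=method,
                evidence=assoc.set_id,
                evidence_name=assoc.name,
                statistic=assoc.p_value,
                statistic_kind=STAT_P,
                seed_genes=assoc.seed_members,
            )
        )
    return rank_predictions(preds)


def _resolve_universe(
    bundle: ReferenceBundle, universe: Optional[set[str]]
) -> set[str]:
    if universe is None:
        return set(bundle.genes)
    unknown = universe - set(bundle.genes)
    if unknown:
        raise ValueError(f"universe contains unknown genes: {sorted(unknown)[:5]}")
    return set(universe)


def cps_seeded(
    space: SearchSpace,
    seeds: set[str],
    bundle: ReferenceBundle,
    alpha: float = DEFAULT_ALPHA,
    sources: Optional[Sequence[str]] = None,
    universe: Optional[set[str]] = None,
    bonferroni: bool = False,
) -> tuple[list[PathwayAssociation], list[CandidatePrediction]]:
    """Seeded pathway scanning.

    Pathways containing at least one seed gene are tested for association
    with the search space; candidates are the non-seed space genes of
    pathways with p below the threshold, prioritized by the lowest pathway
    p-value they share. Seed genes located inside loci count toward the
    overlap k but are never emitted as candidates.
    """
    if not seeds:
        raise ValueError("seeded mode requires at least one seed gene")
    seed_ids = frozenset(s for s in (bundle.resolve_gene(t) for t in seeds) if s)
    uni = _resolve_universe(bundle, universe)
    n = len(space.genes & uni)
    candidates = [gs for gs in bundle.sets_by_source(sources) if gs.members & seed_ids]
    associations = []
    for gs in candidates:
        assoc = _associate(gs, space, uni, n, seed_ids)
        if assoc is not None:
            associations.append(assoc)
    threshold = alpha / len(candidates) if (bonferroni and candidates) else alpha
    for assoc in associations:
        assoc.retained = assoc.p_value < threshold
    associations.sort(key=lambda a: (a.p_value, a.source_db, a.set_id))
    preds = _pathway_predictions(associations, space, bundle, "CPS-s", exclude=seed_ids)
    return associations, preds


def cps_ab_initio(
    space: SearchSpace,
    bundle: ReferenceBundle,
    alpha: float = DEFAULT_ALPHA,
    min_loci: int = DEFAULT_MIN_LOCI,
    sources: Optional[Sequence[str]] = None,
    universe: Optional[set[str]] = None,
    bonferroni: bool = False,
) -> tuple[list[PathwayAssociation], list[CandidatePrediction]]:
    """Ab initio pathway scanning over multiple loci.

    Without seeds, candidate pathways are those whose space overlap spans at
    least ``min_loci`` distinct loci ("common pathways"); association counts
    and ranking are identical to seeded mode, and every space gene of a
    retained pathway is predicted.
    """
    if len(space.loci) < 2:
        raise ValueError("ab initio mode requires >= 2 loci")
    uni = _resolve_universe(bundle, universe)
    n = len(space.genes & uni)
    associations = []
    for gs in bundle.sets_by_source(sources):
        assoc = _associate(gs, space, uni, n, frozenset())
        if assoc is not None and assoc.loci_hit >= min_loci:
            associations.append(assoc)
    threshold = alpha / len(associations) if (bonferroni and associations) else alpha
    for assoc in associations:
        assoc.retained = assoc.p_value < threshold
    associations.sort(key=lambda a: (a.p_value, a.source_db, a.set_id))
    preds = _pathway_predictions(
        associations, space, bundle, "CPS-ab", exclude=frozenset()
    )
    return associations, preds


# ------------------------------------------------------------- PPI evidence

def ppi_seeded(
    space: SearchSpace,
    seeds: set[str],
    bundle: ReferenceBundle,
) -> list[CandidatePrediction]:
    """Non-seed space genes with a direct interaction edge to a seed gene.

    The statistic is the number of distinct seed interactors; reports render
    the score column as "-" for interaction rows.
    """
    seed_ids = frozenset(s for s in (bundle.resolve_gene(t) for t in seeds) if s)
    preds = []
    for gid in sorted(space.genes - seed_ids):
        partners = tuple(sorted(bundle.adjacency.get(gid, set()) & seed_ids))
        if not partners:
            continue
        preds.append(
            CandidatePrediction(
                gene_id=gid,
                symbol=bundle.genes[gid].symbol,
                locus_ids=tuple(sorted(space.loci_of(gid))),
                method="PPI-s",
                evidence=PPIN,
                evidence_name=PPIN,
                statistic=float(len(partners)),
                statistic_kind=STAT_COUNT,
                seed_genes=partners,
            )
        )
    return rank_predictions(preds)


def ppi_ab_initio(
    space: SearchSpace,
    bundle: ReferenceBundle,
) -> list[CandidatePrediction]:
    """Space genes joined by a direct edge across two distinct loci.

    Both endpoints are emitted; the statistic counts a gene's cross-locus
    interaction partners. Edges internal to a single locus are ignored.
    """
    if len(space.loci) < 2:
        raise ValueError("ab initio mode requires >= 2 loci")
    preds = []
    for gid in sorted(space.genes):
        own = space.loci_of(gid)
        partners = []
        for other in sorted(bundle.adjacency.get(gid, set()) & space.genes):
            theirs = space.loci_of(other)
            # cross-locus unless both genes live only in one identical locus
            if theirs - own or own - theirs or len(own) > 1:
                partners.append(other)
        if partners:
            preds.append(
                CandidatePrediction(
                    gene_id=gid,
                    symbol=bundle.genes[gid].symbol,
                    locus_ids=tuple(sorted(own)),
                    method="PPI-ab",
                    evidence=PPIN,
                    evidence_name=PPIN,
                    statistic=float(len(partners)),
                    statistic_kind=STAT_COUNT,
                    seed_genes=(),
                )
            )
    return rank_predictions(preds)


# ---------------------------------------------------------------- ranking

def _sort_key(p: CandidatePrediction) -> tuple:
    if p.statistic_kind == STAT_P:
        return (0, p.statistic, p.symbol, p.evidence)
    if p.statistic_kind == STAT_SCORE:
        return (0, -p.statistic, p.symbol, p.evidence)
    # interaction counts rank after pathway/domain statistics, descending
    return (1, -p.statistic, p.symbol, p.evidence)


def rank_predictions(
    predictions: Sequence[CandidatePrediction],
) -> list[CandidatePrediction]:
    """Assign 1-based relative ranks within each locus.

    Rows are ordered by statistic (p ascending, scores descending, then
    interaction counts descending after the statistical rows) with symbol as
    the deterministic tie-break; a gene's rank is the position of its
    best-scoring row within the locus, and a multi-locus row carries its best
    rank across its loci. Input order never affects the result.
    """
    rows = sorted(predictions, key=_sort_key)
    # positions per locus
    per_locus: dict[str, list[CandidatePrediction]] = {}
    for row in rows:
        for lid in row.locus_ids:
            per_locus.setdefault(lid, []).append(row)
    rank_of: dict[tuple[int, str], int] = {}
    for lid, lrows in per_locus.items():
        gene_best: dict[str, int] = {}
        for pos, row in enumerate(lrows, start=1):
            gene_best.setdefault(row.gene_id, pos)
        for row in lrows:
            key = (id(row), lid)
            rank_of[key] = gene_best[row.gene_id]
    for row in rows:
        ranks = [rank_of[(id(row), lid)] for lid in row.locus_ids]
        row.relative_rank = min(ranks) if ranks else None
    return rows
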