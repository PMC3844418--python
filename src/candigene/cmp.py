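"""Common Module Profiling (CMP): domain-content evidence.

Seeded mode scores a candidate by the sequence similarity of domain
instances it shares (same family) with a known disease gene: each shared
pair of domain subsequences is Smith-Waterman aligned and normalized by the
larger self-alignment score, so the per-gene score S is the best normalized
instance-pair similarity in [0, 1].

Ab initio mode tests domain families (or co-occurring family pairs) for
over-representation across the loci relative to the genome: the family's
observed count is taken both per gene (anti-conservative) and per locus
(conservative — paralog clusters inside one locus collapse to a single
observation), each compared to the same expectation e = n*K/N by a
chi-square component, and the reported statistic chi2_min is the smaller of
the two. A component counts over-representation evidence only, so it is zero
whenever its observed count does not exceed the expectation. Families are
retained when both counts exceed expectation, the locus count reaches
``min_loci`` and chi2_min reaches the threshold (3.84 ~ p 0.05 at 1 df).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

from .alignment import ScoringScheme, default_scheme, smith_waterman
from .bundle import ReferenceBundle
from .cps import rank_predictions
from .loci import SearchSpace
from .models import STAT_SCORE, CandidatePrediction, DomainHit

DEFAULT_CHI2_THRESHOLD = 3.84
DEFAULT_MIN_LOCI = 2

DIRECTION_OVER = "over"
DIRECTION_UNDER = "under"
DIRECTION_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class DomainSimilarity:
    """A scored pairwise comparison of two same-family domain instances."""

    family_id: str
    protein_a: str
    protein_b: str
    raw_score: float
    self_a: float
    self_b: float
    s_norm: float


@dataclass
class DomainEnrichment:
    """Over-representation record for one family (or family combination)."""

    family_id: str  # single family or "FAM1+FAM2" canonical pair
    o_gene: int
    o_locus: int
    e: float
    chi2_gene: float
    chi2_locus: float
    chi2_min: float
    direction: str
    bearing_genes: tuple[str, ...] = ()
    retained: bool = False


def chi2_component(o: float, e: float) -> float:
    """Single chi-square component (o - e)^2 / e; requires e > 0."""
    if e <= 0:
        raise ValueError(f"expected count must be positive, got {e}")
    return (o - e) ** 2 / e


def _evidence_component(o: float, e: float) -> float:
    # over-representation evidence only: no signal when o <= e
    return chi2_component(o, e) if o > e else 0.0


def domain_similarity(
    hit_a: DomainHit,
    hit_b: DomainHit,
    bundle: ReferenceBundle,
    scheme: Optional[ScoringScheme] = None,
) -> DomainSimilarity:
    """Align two same-family domain subsequences and normalize the score.

    s_norm = raw / max(self_a, self_b), which is 1 for identical instances
    and lies in [0, 1] for substitution matrices whose diagonal dominates.
    """
    if hit_a.family_id != hit_b.family_id:
        raise ValueError(
            f"cannot compare different families {hit_a.family_id} vs {hit_b.family_id}"
        )
    scheme = scheme or default_scheme()
    seqs = []
    for hit in (hit_a, hit_b):
        prot = bundle.proteins.get(hit.protein_id)
        if prot is None:
            raise ValueError(f"missing protein sequence for {hit.protein_id}")
        seqs.append(prot.residues[hit.ali_start : hit.ali_end])
    raw = smith_waterman(seqs[0], seqs[1], scheme)
    self_a = smith_waterman(seqs[0], seqs[0], scheme)
    self_b = smith_waterman(seqs[1], seqs[1], scheme)
    denom = max(self_a, self_b)
    s_norm = raw / denom if denom > 0 else 0.0
    return DomainSimilarity(
        family_id=hit_a.family_id,
        protein_a=hit_a.protein_id,
        protein_b=hit_b.protein_id,
        raw_score=raw,
        self_a=self_a,
        self_b=self_b,
        s_norm=min(1.0, s_norm),
    )


def cmp_seeded(
    space: SearchSpace,
    seeds: set[str],
    bundle: ReferenceBundle,
    scheme: Optional[ScoringScheme] = None,
    s_min: float = 0.0,
) -> list[CandidatePrediction]:
    """Score non-seed space genes by domain similarity to the seed genes.

    For every family shared between a candidate and a seed, every instance
    pair (candidate proteins x seed proteins) is compared; the candidate's
    score S is the maximum normalized similarity, carrying the best-scoring
    seed and family as evidence. Results are ranked by S descending within
    each locus. Seed or hit ordering never changes the outcome.
    """
    scheme = scheme or default_scheme()
    seed_ids = sorted(s for s in (bundle.resolve_gene(t) for t in seeds) if s)
    if not bundle.domain_hits:
        import logging

        logging.getLogger("candigene").warning("no domain assignments loaded; CMP-s is empty")
        return []
    seed_fams = {sid: bundle.gene_families(sid) for sid in seed_ids}
    preds = []
    for gid in sorted(space.genes - set(seed_ids)):
        gene_fams = bundle.gene_families(gid)
        best: Optional[tuple[float, str, str]] = None  # (s_norm, family, seed)
        for sid in seed_ids:
            for fam in sorted(gene_fams & seed_fams[sid]):
                for ha in bundle.gene_family_hits(gid, fam):
                    for hb in bundle.gene_family_hits(sid, fam):
                        sim = domain_similarity(ha, hb, bundle, scheme)
                        cand = (sim.s_norm, fam, sid)
                        # deterministic: higher score, then family, then seed
                        if best is None or (cand[0], ) > (best[0], ) or (
                            cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2])
                        ):
                            best = cand
        if best is None or best[0] < s_min:
            continue
        preds.append(
            CandidatePrediction(
                gene_id=gid,
                symbol=bundle.genes[gid].symbol,
                locus_ids=tuple(sorted(space.loci_of(gid))),
                method="CMP-s",
                evidence=best[1],
                evidence_name=best[1],
                statistic=best[0],
                statistic_kind=STAT_SCORE,
                seed_genes=(best[2],),
            )
        )
    return rank_predictions(preds)


# --------------------------------------------------------------- ab initio

def _gene_combos(
    bundle: ReferenceBundle, gene_id: str, combinations_mode: str
) -> set[str]:
    """Domain-family keys carried by a gene: single families, or additionally
    unordered same-protein family pairs in ``pairs`` mode (key "A+B")."""
    combos: set[str] = set()
    for pid in bundle.gene_proteins.get(gene_id, ()):
        fams = sorted({h.family_id for h in bundle.hits_by_protein.get(pid, ())})
        combos.update(fams)
        if combinations_mode == "pairs":
            combos.update("+".join(pair) for pair in combinations(fams, 2))
    return combos


def cmp_ab_initio(
    space: SearchSpace,
    bundle: ReferenceBundle,
    chi2_threshold: float = DEFAULT_CHI2_THRESHOLD,
    min_loci: int = DEFAULT_MIN_LOCI,
    combinations_mode: str = "singles",
    max_family_universe_freq: Optional[float] = None,
    universe: Optional[set[str]] = None,
) -> tuple[list[DomainEnrichment], list[CandidatePrediction]]:
    """Chi-square over-representation of domain families across loci.

    Returns every evaluated enrichment (flagged ``retained``) sorted by
    chi2_min descending, and the predictions: space genes bearing a retained
    family, scored by the family's chi2_min, ranked descending within locus.
    ``max_family_universe_freq`` optionally drops promiscuous families
    present in more than that fraction of the universe.
    """
    if len(space.loci) < 2:
        raise ValueError("ab initio mode requires >= 2 loci")
    if combinations_mode not in ("singles", "pairs"):
        raise ValueError(f"combinations must be 'singles' or 'pairs', got {combinations_mode!r}")
    uni = set(bundle.genes) if universe is None else set(universe)
    N = len(uni)
    space_genes = sorted(space.genes & uni)
    n = len(space_genes)

    combos_by_gene = {gid: _gene_combos(bundle, gid, combinations_mode) for gid in space_genes}
    present = sorted(set().union(*combos_by_gene.values()) if combos_by_gene else set())

    # universe bearer counts for each combo present in the space
    bearer_count: dict[str, int] = {c: 0 for c in present}
    present_set = set(present)
    for gid in uni:
        for combo in _gene_combos(bundle, gid, combinations_mode) & present_set:
            bearer_count[combo] += 1

    enrichments = []
    predictions_by_gene: dict[str, tuple[float, str]] = {}
    for combo in present:
        K = bearer_count[combo]
        if K == 0:
            continue  # family absent from universe is skipped
        if max_family_universe_freq is not None and K / N > max_family_universe_freq:
            continue
        bearing = tuple(g for g in space_genes if combo in combos_by_gene[g])
        o_gene = len(bearing)
        loci = set()
        for gid in bearing:
            loci |= space.loci_of(gid)
        o_locus = len(loci)
        e = n * K / N
        chi2_gene = _evidence_component(o_gene, e)
        chi2_locus = _evidence_component(o_locus, e)
        if o_gene > e and o_locus > e:
            direction = DIRECTION_OVER
        elif o_gene < e and o_locus < e:
            direction = DIRECTION_UNDER
        else:
            direction = DIRECTION_AMBIGUOUS
        enr = DomainEnrichment(
            family_id=combo,
            o_gene=o_gene,
            o_locus=o_locus,
            e=e,
            chi2_gene=chi2_gene,
            chi2_locus=chi2_locus,
            chi2_min=min(chi2_gene, chi2_locus),
            direction=direction,
            bearing_genes=bearing,
        )
        enr.retained = (
            enr.direction == DIRECTION_OVER
            and enr.o_locus >= min_loci
            and enr.chi2_min >= chi2_threshold
        )
        enrichments.append(enr)
        if enr.retained:
            for gid in bearing:
                cur = predictions_by_gene.get(gid)
                cand = (enr.chi2_min, combo)
                if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
                    predictions_by_gene[gid] = cand

    enrichments.sort(key=lambda e: (-e.chi2_min, e.family_id))
    preds = []
    for gid in sorted(predictions_by_gene):
        chi2, combo = predictions_by_gene[gid]
        preds.append(
            CandidatePrediction(
                gene_id=gid,
                symbol=bundle.genes[gid].symbol,
                locus_ids=tuple(sorted(space.loci_of(gid))),
                method="CMP-ab",
                evidence=combo,
                evidence_name=combo,
                statistic=chi2,
                statistic_kind=STAT_SCORE,
                seed_genes=(),
            )
        )
    return enrichments, rank_predictions(preds)
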