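"""Core record types shared by every engine.

All genomic coordinates are 0-based, half-open ``[start, end)``; reports
render 1-based inclusive coordinates at the presentation layer only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

STRANDS = ("+", "-")
MARKER_KINDS = ("snp", "sts")

#: Methods a prediction row may carry (pathway, interaction and domain modes,
#: each in seeded "-s" and ab initio "-ab" flavours).
METHODS = ("CPS-s", "CPS-ab", "PPI-s", "PPI-ab", "CMP-s", "CMP-ab")


@dataclass(frozen=True)
class Gene:
    """A gene with its genomic span."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class ProteinRecord:
    """A protein product tied to its owning gene."""

    protein_id: str
    gene_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein {self.protein_id}: residues must be non-empty")


@dataclass(frozen=True)
class DomainHit:
    """One domain-family assignment on a protein (Pfam-style accession).

    Coordinates are protein residue positions, 0-based half-open. Assignments
    are consumed as input; this package never runs the HMM scan itself.
    """

    protein_id: str
    family_id: str
    ali_start: int
    ali_end: int
    bit_score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.ali_start < self.ali_end):
            raise ValueError(
                f"domain hit {self.family_id}@{self.protein_id}: "
                f"require 0 <= ali_start < ali_end"
            )


@dataclass(frozen=True)
class GeneSet:
    """A named pathway or complex: the unit of shared-pathway evidence."""

    set_id: str
    name: str
    source_db: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id}: members must be non-empty")


@dataclass(frozen=True)
class InteractionEdge:
    """An undirected protein-protein interaction between two genes.

    Stored with ``gene_a <= gene_b``; self edges are rejected.
    """

    gene_a: str
    gene_b: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-edge not allowed: {self.gene_a}")
        if self.gene_a > self.gene_b:
            raise ValueError("edge endpoints must be in canonical (sorted) order")

    @staticmethod
    def make(a: str, b: str, source: str = "") -> "InteractionEdge":
        """Build an edge in canonical endpoint order."""
        if a > b:
            a, b = b, a
        return InteractionEdge(a, b, source)


@dataclass(frozen=True)
class Marker:
    """A mapped genetic marker (SNP or STS)."""

    marker_id: str
    kind: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.kind not in MARKER_KINDS:
            raise ValueError(f"marker {self.marker_id}: kind must be one of {MARKER_KINDS}")
        if self.pos < 0:
            raise ValueError(f"marker {self.marker_id}: pos must be >= 0")


@dataclass(frozen=True)
class PhenotypeRecord:
    """A phenotype with its known (seed) disease genes."""

    phenotype_id: str
    name: str
    seed_genes: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class PhenotypeCluster:
    """Phenotypes merged on a shared name root; seed sets are unioned."""

    name: str
    member_phenotypes: tuple[str, ...]
    seed_genes: frozenset[str]


# Statistic kinds carried by prediction rows. ``p`` ranks ascending,
# ``score`` and ``count`` rank descending; ``count`` rows sort after the
# others within a locus (interaction evidence trails pathway evidence).
STAT_P = "p"
STAT_SCORE = "score"
STAT_COUNT = "count"


@dataclass
class CandidatePrediction:
    """One (gene, loci, method, evidence, statistic) output row.

    Mirrors the report schema: which gene, in which loci, predicted by which
    method, through which shared property, at what score, anchored on which
    seed genes (empty in ab initio modes).
    """

    gene_id: str
    symbol: str
    locus_ids: tuple[str, ...]
    method: str
    evidence: str
    evidence_name: str
    statistic: float
    statistic_kind: str
    seed_genes: tuple[str, ...] = ()
    relative_rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.statistic_kind not in (STAT_P, STAT_SCORE, STAT_COUNT):
            raise ValueError(f"unknown statistic kind {self.statistic_kind!r}")
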