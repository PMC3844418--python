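"""The indexed in-memory reference store.

A :class:`ReferenceBundle` holds the gene annotation, gene sets, interaction
edges, proteins, domain assignments, markers and phenotype seed lists that
every engine consumes, with a per-chromosome interval index over genes. It is
the *universe* for all statistics downstream.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .models import (
    DomainHit,
    Gene,
    GeneSet,
    InteractionEdge,
    Marker,
    PhenotypeCluster,
    PhenotypeRecord,
    ProteinRecord,
)

logger = logging.getLogger("candigene")


class ReferenceError(ValueError):
    """Fatal problem assembling or reading reference data."""


class ReferenceBundle:
    """Validated, indexed store of all reference records.

    Construction resolves every cross-reference: records pointing at unknown
    genes or proteins are dropped with a warning (collected in
    :attr:`load_warnings`), never silently, so the statistical universe stays
    well-defined.
    """

    def __init__(
        self,
        genes: Iterable[Gene],
        proteins: Iterable[ProteinRecord] = (),
        domain_hits: Iterable[DomainHit] = (),
        gene_sets: Iterable[GeneSet] = (),
        edges: Iterable[InteractionEdge] = (),
        markers: Iterable[Marker] = (),
        phenotypes: Iterable[PhenotypeRecord] = (),
    ) -> None:
        self.load_warnings: list[str] = []

        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ReferenceError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        if not self.genes:
            raise ReferenceError("a bundle requires at least one gene")

        self.symbol_to_id: dict[str, str] = {}
        for g in self.genes.values():
            # first-come on symbol collisions; lookups by id always win
            self.symbol_to_id.setdefault(g.symbol, g.gene_id)

        self._chrom_genes: dict[str, list[Gene]] = defaultdict(list)
        for g in self.genes.values():
            self._chrom_genes[g.chrom].append(g)
        for glist in self._chrom_genes.values():
            glist.sort(key=lambda g: (g.start, g.gene_id))
        self._trees: dict[str, IntervalTree] = {
            chrom: IntervalTree.from_tuples(
                (g.start, g.end, g.gene_id) for g in glist
            )
            for chrom, glist in self._chrom_genes.items()
        }

        # proteins: every protein must map to a known gene
        self.proteins: dict[str, ProteinRecord] = {}
        self.gene_proteins: dict[str, list[str]] = defaultdict(list)
        for p in proteins:
            if p.gene_id not in self.genes:
                self._warn(f"protein {p.protein_id}: unknown gene_id {p.gene_id}; dropped")
                continue
            if p.protein_id in self.proteins:
                raise ReferenceError(f"duplicate protein_id {p.protein_id}")
            self.proteins[p.protein_id] = p
            self.gene_proteins[p.gene_id].append(p.protein_id)

        self.domain_hits: list[DomainHit] = []
        self.hits_by_protein: dict[str, list[DomainHit]] = defaultdict(list)
        self.hits_by_family: dict[str, list[DomainHit]] = defaultdict(list)
        for h in domain_hits:
            prot = self.proteins.get(h.protein_id)
            if prot is None:
                self._warn(f"domain hit {h.family_id}: unknown protein {h.protein_id}; dropped")
                continue
            if h.ali_end > len(prot.residues):
                self._warn(
                    f"domain hit {h.family_id}@{h.protein_id}: ali_end {h.ali_end} "
                    f"exceeds protein length {len(prot.residues)}; dropped"
                )
                continue
            self._index_hit(h)

        # gene sets: unresolved members dropped; empty-after-resolution sets dropped
        self.gene_sets: dict[tuple[str, str], GeneSet] = {}
        for gs in gene_sets:
            resolved = []
            for m in sorted(gs.members):
                gid = self.resolve_gene(m)
                if gid is None:
                    self._warn(f"gene set {gs.set_id}: unknown member {m}; dropped member")
                else:
                    resolved.append(gid)
            if not resolved:
                self._warn(f"gene set {gs.set_id}: no resolvable members; dropped set")
                continue
            key = (gs.source_db, gs.set_id)
            if key in self.gene_sets:
                raise ReferenceError(f"duplicate gene set {gs.set_id} in source {gs.source_db}")
            self.gene_sets[key] = GeneSet(gs.set_id, gs.name, gs.source_db, frozenset(resolved))

        self.edges: set[tuple[str, str]] = set()
        self.edge_records: list[InteractionEdge] = []
        self.adjacency: dict[str, set[str]] = defaultdict(set)
        for e in edges:
            if isinstance(e, tuple):  # raw triple from a reader
                a, b, src = e
                if a == b:
                    self._warn(f"self-edge {a}-{b}; dropped")
                    continue
                e = InteractionEdge.make(a, b, src)
            if e.gene_a not in self.genes or e.gene_b not in self.genes:
                self._warn(f"edge {e.gene_a}-{e.gene_b}: unknown gene; dropped")
                continue
            self._index_edge(e)

        self.markers: dict[str, Marker] = {}
        for m in markers:
            if m.marker_id in self.markers:
                raise ReferenceError(f"duplicate marker_id {m.marker_id}")
            self.markers[m.marker_id] = m

        self.phenotypes: dict[str, PhenotypeRecord] = {}
        for ph in phenotypes:
            resolved = set()
            for tok in sorted(ph.seed_genes):
                gid = self.resolve_gene(tok)
                if gid is None:
                    self._warn(f"phenotype {ph.phenotype_id}: unknown seed gene {tok}; dropped")
                else:
                    resolved.add(gid)
            self.phenotypes[ph.phenotype_id] = PhenotypeRecord(
                ph.phenotype_id, ph.name, frozenset(resolved)
            )

    # ------------------------------------------------------------------ utils

    def _warn(self, msg: str) -> None:
        self.load_warnings.append(msg)
        logger.warning(msg)

    def resolve_gene(self, token: str) -> Optional[str]:
        """Resolve a gene id or symbol to a gene_id, or None."""
        if token in self.genes:
            return token
        return self.symbol_to_id.get(token)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chrom_genes)

    def chrom_genes(self, chrom: str) -> list[Gene]:
        """Genes on a chromosome, sorted by (start, gene_id)."""
        return self._chrom_genes.get(chrom, [])

    def sets_by_source(self, sources: Optional[Sequence[str]] = None) -> list[GeneSet]:
        """Gene sets, optionally filtered to the given source labels, sorted."""
        out = [
            gs
            for (src, _sid), gs in self.gene_sets.items()
            if sources is None or src in sources
        ]
        out.sort(key=lambda gs: (gs.source_db, gs.set_id))
        return out

    def gene_families(self, gene_id: str) -> set[str]:
        """Domain families present on any protein of a gene."""
        fams: set[str] = set()
        for pid in self.gene_proteins.get(gene_id, ()):
            for h in self.hits_by_protein.get(pid, ()):
                fams.add(h.family_id)
        return fams

    def gene_family_hits(self, gene_id: str, family_id: str) -> list[DomainHit]:
        """All hits of one family across a gene's proteins."""
        out = []
        for pid in self.gene_proteins.get(gene_id, ()):
            out.extend(h for h in self.hits_by_protein.get(pid, ()) if h.family_id == family_id)
        return out

    # ------------------------------------------------------- mutation helpers

    def _index_hit(self, h: DomainHit) -> None:
        self.domain_hits.append(h)
        self.hits_by_protein[h.protein_id].append(h)
        self.hits_by_family[h.family_id].append(h)

    def _index_edge(self, e: InteractionEdge) -> None:
        key = (e.gene_a, e.gene_b)
        if key in self.edges:
            return
        self.edges.add(key)
        self.edge_records.append(e)
        self.adjacency[e.gene_a].add(e.gene_b)
        self.adjacency[e.gene_b].add(e.gene_a)

    def add_gene_set(self, gs: GeneSet) -> None:
        key = (gs.source_db, gs.set_id)
        if key in self.gene_sets:
            raise ReferenceError(f"duplicate gene set {key}")
        unknown = [m for m in gs.members if m not in self.genes]
        if unknown:
            raise ReferenceError(f"gene set {gs.set_id}: unknown members {sorted(unknown)}")
        self.gene_sets[key] = gs

    def add_edge(self, a: str, b: str, source: str = "") -> None:
        if a not in self.genes or b not in self.genes:
            raise ReferenceError(f"edge {a}-{b}: unknown gene")
        self._index_edge(InteractionEdge.make(a, b, source))

    def add_marker(self, m: Marker) -> None:
        if m.marker_id in self.markers:
            raise ReferenceError(f"duplicate marker_id {m.marker_id}")
        self.markers[m.marker_id] = m

    def add_domain_hit(self, h: DomainHit) -> None:
        prot = self.proteins.get(h.protein_id)
        if prot is None or h.ali_end > len(prot.residues):
            raise ReferenceError(f"invalid domain hit {h.family_id}@{h.protein_id}")
        self._index_hit(h)

    def extend_protein(self, protein_id: str, extra_residues: str) -> None:
        """Append residues to a protein (used when planting a domain)."""
        old = self.proteins[protein_id]
        self.proteins[protein_id] = ProteinRecord(
            old.protein_id, old.gene_id, old.residues + extra_residues
        )

    # -------------------------------------------------------------- queries

    def genes_in_interval(self, chrom: str, start: int, end: int) -> list[Gene]:
        """Genes with any base overlap of ``[start, end)``, sorted by (start, id).

        Unknown chromosome yields an empty list with a warning.
        """
        if start >= end:
            raise ValueError(f"require start < end, got [{start}, {end})")
        tree = self._trees.get(chrom)
        if tree is None:
            logger.warning("genes_in_interval: unknown chromosome %r", chrom)
            return []
        hits = [self.genes[iv.data] for iv in tree.overlap(start, end)]
        hits.sort(key=lambda g: (g.start, g.gene_id))
        return hits


def genes_in_interval(bundle: ReferenceBundle, chrom: str, start: int, end: int) -> list[Gene]:
    """Module-level convenience wrapper around the bundle's interval query."""
    return bundle.genes_in_interval(chrom, start, end)


# --------------------------------------------------------- phenotype merging

_PUNCT_RE = re.compile(r"[^\w\s]")


def _normalize(name: str) -> str:
    return _PUNCT_RE.sub(" ", name.casefold()).strip()


def cluster_phenotypes(
    phenotypes: Sequence[PhenotypeRecord],
    root_tokens: Optional[Sequence[str]] = None,
) -> list[PhenotypeCluster]:
    """Merge phenotypes whose names share a root into one cluster.

    With explicit ``root_tokens``, a phenotype joins the cluster of the first
    token found (case-folded, punctuation-stripped substring match) — e.g. all
    the subtype entries of a disease merge on a single root like "alzheimer".
    Without tokens, phenotypes sharing their leading word of >= 4 characters
    merge. Unmatched phenotypes form singleton clusters; seed sets are
    unioned. The result is a partition of the input phenotype ids, sorted by
    cluster name. Users may deselect individual members afterwards (cluster
    deconstruction) simply by filtering ``member_phenotypes``.
    """
    buckets: dict[tuple[str, str], list[PhenotypeRecord]] = {}
    names: dict[tuple[str, str], str] = {}
    for ph in phenotypes:
        norm = _normalize(ph.name)
        key: Optional[tuple[str, str]] = None
        if root_tokens:
            for tok in root_tokens:
                if tok.casefold() in norm:
                    key = ("token", tok.casefold())
                    names[key] = tok
                    break
        else:
            words = norm.split()
            if words and len(words[0]) >= 4:
                key = ("lead", words[0])
                names[key] = words[0]
        if key is None:
            key = ("singleton", ph.phenotype_id)
            names[key] = ph.name
        buckets.setdefault(key, []).append(ph)

    clusters = [
        PhenotypeCluster(
            name=names[key],
            member_phenotypes=tuple(sorted(ph.phenotype_id for ph in members)),
            seed_genes=frozenset().union(*(ph.seed_genes for ph in members)),
        )
        for key, members in buckets.items()
    ]
    clusters.sort(key=lambda c: (c.name, c.member_phenotypes))
    return clusters
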